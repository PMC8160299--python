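"""Paired regional (WM vs GM) differential analysis and nonparametric tests.

The regional screen follows the fold-change-first logic of the underlying
study: per-region gene means, a >= 2-fold threshold for calling a gene
white-matter- or grey-matter-biased, and exact nonparametric tests on the
per-donor values as supporting inference. Multiple testing is controlled by
Benjamini-Hochberg across the analyzed panel but never gates the fold-change
direction call.

The two tests are the Wilcoxon signed-rank test (paired; Wilcoxon's
zero-drop convention, midranks for tied magnitudes) and the Mann-Whitney U
test (unpaired; midranks). Small samples use exact p-values by complete
enumeration — all 2^n sign assignments for the signed-rank test up to
n_effective = 12, all C(n+m, n) group labelings for Mann-Whitney up to
n = m = 8 with no cross-group ties — and larger samples use the tie- and
continuity-corrected normal approximation. Two-sided p-values double the
smaller tail probability, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu as _scipy_mwu
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleTable, ValidationError

#: Largest n_effective for which the signed-rank test enumerates all 2^n
#: sign assignments (4096 assignments — instantaneous).
EXACT_SIGNED_RANK_LIMIT = 12
#: Largest per-group size for which Mann-Whitney enumerates all C(n+m, n)
#: labelings (C(16, 8) = 12870 — instantaneous).
EXACT_MWU_LIMIT = 8


@dataclass(frozen=True)
class TestResult:
    statistic: float
    n_effective: int
    p_value: float
    method: str
    sided: str = "two_sided"
    degenerate: bool = False


def _two_sided_from_distribution(values: np.ndarray, observed: float) -> float:
    """Double the smaller exact tail of an enumerated null distribution."""
    total = values.size
    lo = np.sum(values <= observed + 1e-9) / total
    hi = np.sum(values >= observed - 1e-9) / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_signed_rank(paired_differences: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's convention); tied magnitudes
    receive midranks. All differences zero is not an error but a degenerate
    result with p = 1. Exact p by enumeration of all sign assignments for
    n_effective <= 12, else normal approximation with tie correction and a
    0.5 continuity correction.
    """
    d = np.asarray(paired_differences, dtype=float)
    if d.size == 0:
        raise ValidationError("no paired differences supplied")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(
            statistic=0.0, n_effective=0, p_value=1.0,
            method="wilcoxon_signed_rank_degenerate", degenerate=True,
        )
    ranks = rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_SIGNED_RANK_LIMIT:
        # all 2^n sign assignments: row i of `signs` is the binary expansion of i
        signs = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
        dist = signs @ ranks
        p = _two_sided_from_distribution(dist, w_plus)
        return TestResult(w_plus, n, p, "wilcoxon_signed_rank_exact")
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
    if var <= 0:
        return TestResult(w_plus, n, 1.0, "wilcoxon_signed_rank_normal", degenerate=True)
    sd = np.sqrt(var)
    # continuity correction: shrink the deviation from the mean by 0.5
    delta = abs(w_plus - mean)
    z = max(0.0, delta - 0.5) / sd
    p = float(min(1.0, 2.0 * norm.sf(z)))
    return TestResult(w_plus, n, p, "wilcoxon_signed_rank_normal")


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test (midranks) on two independent groups.

    Exact p by enumeration of all C(n+m, n) group labelings when both groups
    have <= 8 observations and no tied value spans the two groups; otherwise
    the tie-corrected, continuity-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    n, m = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = rankdata(combined, method="average")
    u_a = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    cross_ties = bool(set(a) & set(b))
    if n <= EXACT_MWU_LIMIT and m <= EXACT_MWU_LIMIT and not cross_ties:
        idx = np.array(list(combinations(range(n + m), n)))
        dist = ranks[idx].sum(axis=1) - n * (n + 1) / 2.0
        p = _two_sided_from_distribution(dist, u_a)
        return TestResult(u_a, n + m, p, "mann_whitney_exact")
    if np.all(combined == combined[0]):
        return TestResult(u_a, n + m, 1.0, "mann_whitney_normal", degenerate=True)
    res = _scipy_mwu(a, b, alternative="two-sided", method="asymptotic", use_continuity=True)
    return TestResult(u_a, n + m, float(res.pvalue), "mann_whitney_normal")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; q >= p, monotone when sorted."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        bad = p[(~np.isfinite(p)) | (p <= 0) | (p > 1)][0]
        raise ValidationError(f"p-value {bad!r} outside (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(
    mean_a: float, mean_b: float, pseudocount: Optional[float] = None
) -> float:
    """log2((mean_a + eps) / (mean_b + eps)).

    ``pseudocount`` defaults to half the smaller nonzero of the two means
    (callers doing a panel-wide analysis should pass a common epsilon —
    half the smallest nonzero mean in the analysis). Two zero means give 0.
    """
    if mean_a < 0 or mean_b < 0:
        raise ValidationError("fold change requires non-negative means")
    if pseudocount is None:
        nonzero = [v for v in (mean_a, mean_b) if v > 0]
        if not nonzero:
            return 0.0
        pseudocount = min(nonzero) / 2.0
    return float(np.log2((mean_a + pseudocount) / (mean_b + pseudocount)))


@dataclass
class RegionDiffResult:
    """Per-gene WM-vs-GM screen: means, fold change, direction call, tests.

    ``table`` columns: mean_WM, mean_GM, log2_fold_change, direction
    (WM_higher / GM_higher / none), p, q, n_effective, method.
    """

    table: pd.DataFrame
    fc_threshold: float
    paired: bool
    pseudocount: float

    @property
    def wm_higher(self) -> list[str]:
        return list(self.table.index[self.table["direction"] == "WM_higher"])

    @property
    def gm_higher(self) -> list[str]:
        return list(self.table.index[self.table["direction"] == "GM_higher"])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")


def region_differential(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    genes: Optional[Sequence[str]] = None,
    fc_threshold: float = 2.0,
    paired: Optional[bool] = None,
) -> RegionDiffResult:
    """WM-vs-GM differential screen over a gene panel.

    Direction is called from the fold change of region means at
    ``fc_threshold`` (>= 2-fold by default). When ``paired`` (default: auto,
    on when every donor has both regions) and at least 4 donors are present,
    a Wilcoxon signed-rank test runs on per-donor WM-GM values; otherwise a
    Mann-Whitney U test on the per-sample values. q-values are BH-adjusted
    over the tested panel and reported alongside, not used for the call.
    """
    meta = samples.table.set_index("sample_id")
    present = [s for s in matrix.sample_ids if s in meta.index]
    if len(present) != matrix.n_samples:
        missing = sorted(set(matrix.sample_ids) - set(meta.index))
        raise ValidationError(f"samples without metadata: {missing[:10]}")
    region = meta.loc[matrix.sample_ids, "region"]
    wm_samples = [s for s in matrix.sample_ids if region[s] == "WM"]
    gm_samples = [s for s in matrix.sample_ids if region[s] == "GM"]
    if not wm_samples or not gm_samples:
        raise ValidationError(
            f"both regions required: {len(wm_samples)} WM / {len(gm_samples)} GM samples"
        )

    donors_wm = set(meta.loc[wm_samples, "donor_id"])
    donors_gm = set(meta.loc[gm_samples, "donor_id"])
    matched = sorted(donors_wm & donors_gm)
    if paired is None:
        paired = donors_wm == donors_gm and len(matched) >= 2
    if paired and donors_wm != donors_gm:
        unmatched = sorted(donors_wm ^ donors_gm)
        raise ValidationError(
            f"paired analysis requested but donors unmatched across regions: {unmatched}"
        )

    if genes is None:
        genes = matrix.gene_ids
    missing_genes = [g for g in genes if g not in matrix.values.index]
    if missing_genes:
        raise ValidationError(f"genes absent from matrix: {missing_genes[:10]}")
    sub = matrix.values.loc[list(genes)]

    mean_wm = sub[wm_samples].mean(axis=1)
    mean_gm = sub[gm_samples].mean(axis=1)
    all_means = np.concatenate([mean_wm.to_numpy(), mean_gm.to_numpy()])
    nonzero = all_means[all_means > 0]
    eps = nonzero.min() / 2.0 if nonzero.size else 1.0

    log2fc = np.array(
        [fold_change(a, b, eps) for a, b in zip(mean_wm, mean_gm)]
    )
    log2_thresh = np.log2(fc_threshold)
    direction = np.where(
        log2fc >= log2_thresh, "WM_higher",
        np.where(log2fc <= -log2_thresh, "GM_higher", "none"),
    )

    p_vals, n_eff, methods = [], [], []
    if paired and len(matched) >= 4:
        wm_by_donor = sub[wm_samples].T.groupby(meta.loc[wm_samples, "donor_id"]).mean().T
        gm_by_donor = sub[gm_samples].T.groupby(meta.loc[gm_samples, "donor_id"]).mean().T
        diffs = wm_by_donor[matched].to_numpy() - gm_by_donor[matched].to_numpy()
        for row in diffs:
            res = wilcoxon_signed_rank(row)
            p_vals.append(res.p_value)
            n_eff.append(res.n_effective)
            methods.append(res.method)
    else:
        wm_arr = sub[wm_samples].to_numpy()
        gm_arr = sub[gm_samples].to_numpy()
        for wa, ga in zip(wm_arr, gm_arr):
            res = mann_whitney_u(wa, ga)
            p_vals.append(res.p_value)
            n_eff.append(res.n_effective)
            methods.append(res.method)
    q_vals = bh_adjust(p_vals)

    table = pd.DataFrame(
        {
            "mean_WM": mean_wm,
            "mean_GM": mean_gm,
            "log2_fold_change": log2fc,
            "direction": direction,
            "p": p_vals,
            "q": q_vals,
            "n_effective": n_eff,
            "method": methods,
        },
        index=pd.Index(list(genes), name="gene"),
    )
    return RegionDiffResult(
        table=table, fc_threshold=fc_threshold, paired=bool(paired), pseudocount=eps
    )
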