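# Methods

## Percentile-rank profiling

A gene's expression level within one dataset is summarized as its percentile
among all N genes of that dataset's matrix: per-gene means across samples
are midranked (ties share the average of the ranks they occupy) and divided
by N. The top gene sits at exactly 1.0; a full N-way tie puts every gene at
(N+1)/(2N). Because only ranks enter, FPKM, TPM and count matrices are
directly comparable, and any strictly increasing transform of the ranked
values leaves the profile unchanged.

Two aggregation orders are provided. `mean_then_rank` (default) averages
each gene across samples and ranks the means once — less sensitive to
per-sample noise. `rank_then_mean` computes per-sample percentiles and
averages them — preferable when samples differ grossly in distribution
shape. Both are exposed because the choice is not dictated by the statistic
itself; all shipped analyses use the default. The denominator N includes
zero-expression genes present in the matrix; users who want a
detected-genes-only background should pre-filter before profiling.

Tiers bin the percentile: below_cutoff (< 0.50), low [0.50, 0.68),
medium [0.68, 0.86), high [0.86, 1.0]. The published two-decimal band edges
(0.67/0.68, 0.85/0.86) are read as roundings of continuous boundaries and
implemented as half-open intervals on unrounded percentiles, so no
percentile falls between bands.

## Gene catalog

The catalog ships as a versioned CSV snapshot (GRAFS families for GPCRs;
G-protein alpha subunits, GRKs and arrestins as signaling categories) for
human and mouse, with alias resolution and cross-species mapping
(case-normalized symbol equality, with an explicit exception column for
pairs like MRGPRX2 ↔ Mrgprb2, and an absent-marker for genes without a
counterpart, e.g. P2RY8). The snapshot covers the microglial core signature,
every gene the analyses touch and a small padding set so that each GRAFS
family is represented; its family counts are snapshot metadata, not a claim
of GPCRome completeness. One curation note: published accounts name only 14
of the 15 genes that pass the consensus unanimously; the snapshot's 15th,
P2RY6, is a documented stand-in chosen from the microglial sensome
(a UDP receptor involved in microglial phagocytosis).

## Consensus core set and the white-matter rescue rule

A catalog GPCR gene joins the core set when it reaches `min_tier` (default
medium) in at least `ceil(min_fraction × D)` of D dataset profiles (default
fraction 1.0 — all datasets). Both knobs are configuration because
"abundant across datasets" fixes neither; the effective rule is echoed into
every report header. The rescue route admits genes that miss the consensus
but are medium in a designated grey-matter profile and high in the paired
white-matter profile; rescue is restricted to that designated (GM, WM) pair
rather than any profile pair, and a rescued gene is flagged separately from
consensus members. Membership is monotone: lowering `min_tier` or
`min_fraction` can only grow the set. Output is independent of the order in
which profiles are supplied.

## Regional differential screen

Per gene, WM and GM means are compared as
`log2((mean_WM + ε) / (mean_GM + ε))` with ε = half the smallest nonzero
mean in the analyzed panel, and a direction (WM_higher / GM_higher) is
called when the fold change reaches the threshold (default 2-fold). The
direction call is fold-change-based by design; hypothesis tests are
reported alongside but do not gate it, keeping effect-size screening
separate from inference. When donors are matched across regions (and ≥ 4),
a Wilcoxon signed-rank test runs on per-donor WM−GM values; otherwise a
Mann-Whitney U test on per-sample values. Benjamini–Hochberg q-values are
computed across the tested panel (via statsmodels).

## Exact nonparametric tests

Both tests use midranks for ties and report two-sided p-values as twice the
smaller tail probability, capped at 1.

* **Wilcoxon signed-rank.** Zero differences are dropped (Wilcoxon's
  convention; `n_effective` counts the nonzero differences, and an all-zero
  input is a degenerate p = 1 result, not an error). For n_effective ≤ 12
  the null distribution of W⁺ is enumerated over all 2ⁿ sign assignments;
  above that, a normal approximation with tie-corrected variance
  n(n+1)(2n+1)/24 − Σ(t³−t)/48 and a 0.5 continuity correction.
* **Mann-Whitney U.** For group sizes ≤ 8 with no tied value spanning the
  groups, the null distribution of U is enumerated over all C(n+m, n)
  labelings; otherwise the tie- and continuity-corrected normal
  approximation (scipy's asymptotic method).

The enumeration limits (12; 8/8) keep the exact computation well under a
second. Reference points: differences [1, 2, 3] give W⁺ = 6, p = 0.25;
groups [1, 2] vs [3, 4] give U = 0, p = 1/3.

## Single-cell summaries and contrasts

Counts are depth-normalized to 10,000 per cell and log(1 + x)-transformed —
a standard, depth-invariant choice stated here as the package's contract.
Cells with zero total counts are excluded with a warning. Cluster summaries
report mean normalized expression and the fraction of cells with count > 0
per (cluster, gene). Contrasts between two labeled clusters run a
Mann-Whitney U test per panel gene across cells (rank-equivalent on the log
or linear scale), BH-adjust across the panel, and call a direction when
|log2FC| ≥ log2(threshold) **and** q < α (defaults 2-fold, 0.05). The fold
change is computed on the linear CP10k cluster means, not the log-mean,
so it tracks the underlying count fold change instead of being compressed
by the log1p transform. The contrast is cell-level, not pseudobulk —
appropriate for data without per-donor structure, but note that cells are
then treated as independent replicates. Embeddings and cluster labels are
inputs throughout; the package never computes a t-SNE/UMAP or clustering.

## Synthetic data

The generators emulate the statistical structure of the real inputs, not
their content:

* **Bulk.** Background gene means are log-normal(meanlog 1.0, sdlog 1.5) —
  heavy-tailed like FPKM/TPM distributions. Planted genes are inserted
  strictly between the background order statistics bracketing rank
  round(p·N), so their post-insertion midrank/N equals the target exactly
  (feasible targets form the grid k/N; a tie block at the requested slot is
  an infeasibility error). Per-(gene, sample) multiplicative log-noise is
  applied on top; the default sd is 0.002 with 8 samples. This default is
  deliberately technical-scale jitter: the generator's contract is that a
  planted midrank remains recoverable to within about one rank slot, and
  with a heavy-tailed background at N ≈ 10³ the spacing between neighboring
  order statistics is ~1% in log space, which bounds how much independent
  per-gene noise the planting contract tolerates. Biological-scale noise is
  available by raising `noise_sd`, at the stated cost in rank stability.
* **Paired regions.** Each donor draws a shared per-(gene, donor) baseline
  (log-noise sd 0.10 by default — it cancels in paired differences), WM
  samples multiply the planted fold changes on top, and measurement jitter
  is added per sample. Defaults: 8 donors, one WM and one GM sample each.
* **Single cell.** Negative-binomial counts via Gamma-Poisson mixing
  (shape = dispersion, default 2.0; var = m + m²/θ), per-cell log-normal
  depth factors (sd 0.3), cluster sizes from fixed proportions, marker
  shifts multiplying per-cluster means, and a deterministic Gaussian-blob
  pseudo-embedding (embeddings are analysis inputs, so the generator
  supplies one).

All generators are pure functions of (spec, seed): equal seeds give
byte-identical artifacts.

### The paper-mirror scenario

`data/paper_mirror.yaml` fixes one narrative fixture used by the end-to-end
tests and the report command: five bulk datasets of 800 genes × 6 samples
(three whole-tissue, one GM, one WM), 15 core genes planted in the high band
(0.91–0.995), CXCR4 and PTGER4 planted medium in GM (0.73–0.81), high in WM
and low elsewhere, and all remaining catalog GPCRs kept at least 0.05
percentile below the medium boundary so tier assignments cannot flip under
the default jitter; an 8-donor paired regional dataset with 2.5× WM effects
on CXCR4/PTGER4 and a 1.5× negative control (ADGRE5); and a 1,600-cell
single-cell dataset (75% homeostatic, 10% disease-associated, 10%
monocytes, 5% lymphocytes) with the six homeostatic markers shifted 0.3×
and CXCR4 3× in the disease cluster (and in monocytes). Problem sizes (800
genes, 6–8 samples, 1,600 cells) are desk-scale choices that keep the full
suite fast while leaving comfortable margins for every planted effect.

What passing on this scenario does **not** show: recovery under
biological-scale inter-sample variability, unit conversion artifacts,
batch effects, ambient RNA/doublets, or catalog incompleteness. The
scenario is a correctness fixture for the pipeline's logic, not a power
study.

## Numerical and edge-case conventions

* Percentile of the maximum is exactly 1.0; percentiles live in (0, 1].
* A single-gene matrix has no percentile (error); an all-zero matrix has no
  relative intensity (error).
* Relative heatmap intensity is log2((x + ε)/(μ_sample + ε)) with ε = half
  the smallest nonzero matrix value, so a gene at its sample's all-gene
  mean maps to 0.
* Duplicate gene rows on read collapse by summation (multi-transcript
  collapsing), with a logged count.
* Fold changes of two zero means are 0 by the pseudocount symmetry.
* TPM columns deviating > 1% from 10⁶ warn but do not fail (filtered
  matrices are legitimate inputs).
* BH q-values satisfy q ≥ p and are permutation-invariant; flat-block
  outputs of the step-up are fixed points of re-adjustment.

## Known limitations

* The catalog is a curated snapshot, not the full non-sensory GPCRome;
  analyses are restricted to its gene universe.
* Cross-species comparison assumes the symbol-equality ortholog rule except
  where the exception table says otherwise; paralog fan-outs are not
  modeled.
* The single-cell contrast treats cells as independent; donor-level
  pseudobulk replication is out of scope.
* The exact Mann-Whitney branch declines instances with cross-group ties
  (midrank enumeration would still be valid but the normal branch is used
  for a fixed, documented contract).
* Count-model differential expression (negative-binomial GLMs), batch
  correction, clustering and embedding computation are out of scope.
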