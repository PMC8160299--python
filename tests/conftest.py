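"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own code paths: midranks
by O(N^2) pairwise comparison, exact test p-values by itertools enumeration.
They exist so the implementation can be checked against something it does
not share a line with.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest

from gpcrome import load_catalog
from gpcrome.profiling import PercentileProfile, Tier, TierScheme, assign_tier


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def oracle_midranks(values) -> np.ndarray:
    """Midrank of each value by explicit pairwise comparison (O(N^2))."""
    values = np.asarray(values, dtype=float)
    n = values.size
    out = np.empty(n)
    for i in range(n):
        less = sum(1 for j in range(n) if values[j] < values[i])
        equal = sum(1 for j in range(n) if values[j] == values[i])
        out[i] = less + (equal + 1) / 2.0
    return out


def oracle_midranks_pairwise(values) -> np.ndarray:
    """Vectorized O(N^2) pairwise midranks (same definition, array form)."""
    v = np.asarray(values, dtype=float)
    less = (v[None, :] < v[:, None]).sum(axis=1)
    equal = (v[None, :] == v[:, None]).sum(axis=1)
    return less + (equal + 1) / 2.0


def _midranks_small(values):
    # shared by the two test oracles; pairwise like oracle_midranks
    return oracle_midranks(values)


def oracle_signed_rank_p(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating every sign assignment."""
    d = [x for x in diffs if x != 0]
    if not d:
        return 1.0
    ranks = _midranks_small([abs(x) for x in d])
    observed = sum(r for r, x in zip(ranks, d) if x > 0)
    dist = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([False, True], repeat=len(d))
    ]
    total = len(dist)
    lo = sum(1 for w in dist if w <= observed + 1e-9) / total
    hi = sum(1 for w in dist if w >= observed - 1e-9) / total
    return min(1.0, 2.0 * min(lo, hi))


def oracle_mwu_p(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating every group labeling."""
    a, b = list(a), list(b)
    n = len(a)
    pooled = a + b
    ranks = _midranks_small(pooled)
    observed = sum(ranks[:n]) - n * (n + 1) / 2.0
    dist = [
        sum(ranks[i] for i in idx) - n * (n + 1) / 2.0
        for idx in combinations(range(len(pooled)), n)
    ]
    total = len(dist)
    lo = sum(1 for u in dist if u <= observed + 1e-9) / total
    hi = sum(1 for u in dist if u >= observed - 1e-9) / total
    return min(1.0, 2.0 * min(lo, hi))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


def make_profile(
    percentiles: dict[str, float],
    dataset_id: str = "ds",
    species: str = "human",
    region: str | None = None,
    scheme: TierScheme = TierScheme(),
) -> PercentileProfile:
    """Build a profile directly from stated per-gene percentiles."""
    genes = list(percentiles)
    pct = np.array([percentiles[g] for g in genes])
    n = len(genes)
    table = pd.DataFrame(
        {
            "mean_expression": pct,  # any monotone stand-in
            "midrank": pct * n,
            "percentile": pct,
            "tier": [int(assign_tier(p, scheme)) for p in pct],
        },
        index=pd.Index(genes, name="gene"),
    )
    return PercentileProfile(
        dataset_id=dataset_id, species=species, table=table,
        scheme=scheme, region=region,
    )
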