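"""Percentile profiling: midrank statistics, tiers, union filter, heatmap values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_profile, oracle_midranks
from gpcrome import (
    Tier,
    TierScheme,
    ValidationError,
    assign_tier,
    gene_percentiles,
    read_profile_tsv,
    relative_intensity,
    species_union_filter,
)
from test_io import matrix_from


def profile_of(means, **kwargs):
    m = matrix_from(np.asarray(means, dtype=float)[:, None])
    return gene_percentiles(m, **kwargs)


class TestGenePercentiles:
    def test_distinct_means(self):
        p = profile_of([10, 20, 30, 40])
        np.testing.assert_allclose(p.table["percentile"], [0.25, 0.50, 0.75, 1.00])

    def test_tied_means_get_midranks(self):
        # midranks (1.5, 1.5, 3, 4) over 4 genes
        p = profile_of([5, 5, 10, 20])
        np.testing.assert_allclose(p.table["percentile"], [0.375, 0.375, 0.75, 1.00])

    def test_full_tie(self):
        n = 7
        p = profile_of([3.0] * n)
        np.testing.assert_allclose(p.table["percentile"], (n + 1) / (2 * n))

    def test_mean_percentile_invariant(self):
        rng = np.random.default_rng(5)
        m = matrix_from(rng.lognormal(1, 1.5, size=(501, 3)))
        for agg in ("mean_then_rank", "rank_then_mean"):
            p = gene_percentiles(m, aggregation=agg)
            n = p.n_genes
            assert p.table["percentile"].mean() == pytest.approx((n + 1) / (2 * n))

    def test_midrank_sum(self):
        rng = np.random.default_rng(6)
        m = matrix_from(np.round(rng.lognormal(1, 1.5, size=(200, 2)), 1))
        p = gene_percentiles(m)
        n = p.n_genes
        assert p.table["midrank"].sum() == pytest.approx(n * (n + 1) / 2)

    def test_single_gene_matrix_is_error(self):
        with pytest.raises(ValidationError, match="single-gene"):
            profile_of([1.0])

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(7)
        values = np.round(rng.lognormal(1.0, 1.5, 150), 1)  # rounding forces ties
        p = profile_of(values)
        np.testing.assert_array_equal(
            p.table["midrank"].to_numpy(), oracle_midranks(values)
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16), n=st.integers(2, 60))
    def test_rank_invariance_under_monotone_transform(self, seed, n):
        """Percentiles are a rank statistic: a strictly increasing transform
        of the ranked values leaves them unchanged (applied per sample for
        rank_then_mean; mean_then_rank ranks the per-gene means, so the
        invariance is over transforms of those means — exercised with a
        single sample)."""
        rng = np.random.default_rng(seed)
        values = np.round(rng.normal(2, 1, size=(n, 3)), 2)
        values -= values.min() - 1.0
        a = gene_percentiles(matrix_from(values), aggregation="rank_then_mean")
        b = gene_percentiles(
            matrix_from(np.exp(values)), aggregation="rank_then_mean"
        )
        np.testing.assert_allclose(
            a.table["percentile"], b.table["percentile"], atol=1e-12
        )
        c = gene_percentiles(matrix_from(values[:, :1]))
        d = gene_percentiles(matrix_from(np.exp(values[:, :1])))
        np.testing.assert_allclose(
            c.table["percentile"], d.table["percentile"], atol=1e-12
        )

    def test_permuting_genes_permutes_profile(self):
        rng = np.random.default_rng(8)
        values = rng.lognormal(1, 1.5, size=(40, 2))
        genes = [f"G{i}" for i in range(40)]
        perm = rng.permutation(40)
        a = gene_percentiles(matrix_from(values, genes=genes))
        b = gene_percentiles(
            matrix_from(values[perm], genes=[genes[i] for i in perm])
        )
        pd.testing.assert_series_equal(
            a.table["percentile"].sort_index(), b.table["percentile"].sort_index()
        )

    def test_rank_then_mean_averages_per_sample_percentiles(self):
        values = np.array([[1.0, 4.0], [2.0, 3.0], [3.0, 2.0], [4.0, 1.0]])
        p = gene_percentiles(matrix_from(values), aggregation="rank_then_mean")
        # every gene is rank 1..4 in one sample and 4..1 in the other
        np.testing.assert_allclose(p.table["percentile"], 0.625)

    def test_profile_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        m = matrix_from(rng.lognormal(1, 1.5, size=(50, 3)))
        p = gene_percentiles(m, region="WM")
        p.to_tsv(tmp_path / "p.tsv")
        back = read_profile_tsv(tmp_path / "p.tsv")
        assert back.region == "WM"
        assert back.dataset_id == p.dataset_id
        np.testing.assert_allclose(
            back.table["percentile"], p.table["percentile"], rtol=1e-9
        )
        assert list(back.table["tier"]) == list(p.table["tier"])


class TestAssignTier:
    @pytest.mark.parametrize(
        "pct,tier",
        [
            (0.90, Tier.high),
            (0.86, Tier.high),
            (1.00, Tier.high),
            (0.85, Tier.medium),
            (0.70, Tier.medium),
            (0.68, Tier.medium),
            (0.67, Tier.low),
            (0.50, Tier.low),
            (0.49, Tier.below_cutoff),
            (0.01, Tier.below_cutoff),
        ],
    )
    def test_boundaries(self, pct, tier):
        assert assign_tier(pct) is tier

    @pytest.mark.parametrize("pct", [0.0, -0.1, 1.0001])
    def test_out_of_range_is_error(self, pct):
        with pytest.raises(ValidationError):
            assign_tier(pct)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValidationError):
            TierScheme(cutoff=0.9, low_upper=0.5, medium_upper=0.86)

    def test_grid_partitions_into_four_contiguous_tiers(self):
        grid = (np.arange(1, 10_001) / 10_000.0)
        tiers = np.array([int(assign_tier(p)) for p in grid])
        # contiguous, ordered blocks
        assert np.all(np.diff(tiers) >= 0)
        assert set(tiers) == {0, 1, 2, 3}


class TestSpeciesUnionFilter:
    def test_or_rule_and_species_specific_flag(self, catalog):
        human = make_profile(
            {"P2RY12": 0.60, "CX3CR1": 0.30, "GPR34": 0.30, "P2RY8": 0.70},
            dataset_id="h", species="human",
        )
        mouse = make_profile(
            {"P2ry12": 0.30, "Cx3cr1": 0.30, "Gpr34": 0.90},
            dataset_id="m", species="mouse",
        )
        out = species_union_filter(human, mouse, catalog)
        assert "P2RY12" in out.index      # 0.60 human / 0.30 mouse -> OR keeps it
        assert "CX3CR1" not in out.index  # 0.30 / 0.30 -> excluded
        assert "GPR34" in out.index       # mouse side carries it
        assert "P2RY8" in out.index       # human-only gene, evaluated alone
        assert bool(out.loc["P2RY8", "species_specific"])
        assert not bool(out.loc["P2RY12", "species_specific"])

    def test_same_species_is_error(self, catalog):
        a = make_profile({"P2RY12": 0.9}, species="human")
        b = make_profile({"CX3CR1": 0.9}, dataset_id="b", species="human")
        with pytest.raises(ValidationError):
            species_union_filter(a, b, catalog)


class TestRelativeIntensity:
    def test_gene_at_sample_mean_is_zero(self):
        m = matrix_from([[1.0], [2.0], [3.0]])  # mean 2
        rel = relative_intensity(m)
        assert rel.iloc[1, 0] == pytest.approx(0.0, abs=1e-9)

    def test_twice_the_mean_is_about_one(self):
        m = matrix_from([[8.0], [1.0], [3.0]])  # sample mean 4, first gene at 8
        rel = relative_intensity(m, pseudocount=1e-9)
        assert rel.iloc[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_ordering_matches_expression_within_sample(self):
        rng = np.random.default_rng(10)
        m = matrix_from(rng.lognormal(0, 1, size=(30, 4)))
        rel = relative_intensity(m)
        for j in range(4):
            x = m.values.iloc[:, j].to_numpy()
            r = rel.iloc[:, j].to_numpy()
            assert np.array_equal(np.argsort(x, kind="stable"), np.argsort(r, kind="stable"))

    def test_all_zero_matrix_is_error(self):
        with pytest.raises(ValidationError, match="all-zero"):
            relative_intensity(matrix_from(np.zeros((3, 2))))
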