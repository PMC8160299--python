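"""Nonparametric tests, fold changes, BH adjustment, regional screen."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import wilcoxon as scipy_wilcoxon

from conftest import oracle_mwu_p, oracle_signed_rank_p
from gpcrome import (
    ValidationError,
    bh_adjust,
    fold_change,
    mann_whitney_u,
    region_differential,
    wilcoxon_signed_rank,
)
from gpcrome.simulate import (
    SyntheticBulkSpec,
    SyntheticRegionSpec,
    simulate_paired_regions,
)


class TestWilcoxonSignedRank:
    def test_worked_example(self):
        res = wilcoxon_signed_rank([1, 2, 3])
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(0.25)
        assert res.method == "wilcoxon_signed_rank_exact"

    def test_tied_magnitudes(self):
        res = wilcoxon_signed_rank([1, -1])
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank([0, 0, 0])
        assert res.p_value == 1.0
        assert res.degenerate
        assert res.n_effective == 0

    def test_zeros_dropped_from_n_effective(self):
        res = wilcoxon_signed_rank([0, 1, 2, 0, 3])
        assert res.n_effective == 3
        assert res.p_value == pytest.approx(0.25)

    def test_empty_input_is_error(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank([])

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = rng.integers(4, 12)
            d = rng.normal(0.3, 1, n)
            while len(set(np.abs(d))) < n or (d == 0).any():
                d = rng.normal(0.3, 1, n)
            ours = wilcoxon_signed_rank(d)
            ref = scipy_wilcoxon(d, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        diffs=st.lists(
            st.integers(-6, 6), min_size=1, max_size=10
        )
    )
    def test_matches_enumeration_oracle_with_ties_and_zeros(self, diffs):
        ours = wilcoxon_signed_rank(diffs)
        assert ours.p_value == pytest.approx(oracle_signed_rank_p(diffs), abs=1e-12)

    def test_normal_approximation_above_exact_limit(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.5, 1, 40)
        res = wilcoxon_signed_rank(d)
        assert res.method == "wilcoxon_signed_rank_normal"
        assert 0 < res.p_value <= 1


class TestMannWhitneyU:
    def test_worked_example(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "mann_whitney_exact"

    def test_identical_groups_give_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_empty_group_is_error(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**16),
        n=st.integers(2, 8),
        m=st.integers(2, 8),
    )
    def test_matches_enumeration_oracle(self, seed, n, m):
        rng = np.random.default_rng(seed)
        a = np.round(rng.normal(0, 1, n), 2)
        b = np.round(rng.normal(0.5, 1, m), 2)
        if set(a) & set(b):  # cross-group tie: implementation switches branch
            return
        ours = mann_whitney_u(a, b)
        assert ours.method == "mann_whitney_exact"
        assert ours.p_value == pytest.approx(oracle_mwu_p(a, b), abs=1e-12)

    def test_cross_group_ties_use_normal_branch(self):
        res = mann_whitney_u([1, 2, 3], [3, 4, 5])
        assert res.method == "mann_whitney_normal"
        assert 0 < res.p_value <= 1

    def test_antisymmetry_of_p_under_group_swap(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 7)
        assert mann_whitney_u(a, b).p_value == pytest.approx(
            mann_whitney_u(b, a).p_value, rel=1e-12
        )


class TestBHAdjust:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_q_at_least_p_and_permutation_invariant(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(1e-6, 1, 50)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p[perm]), q[perm])

    def test_fixed_points_are_stable(self):
        # flat blocks (the step-up's typical output shape) are fixed points
        for q in ([0.03, 0.03, 0.03], [1.0, 1.0], [0.5]):
            np.testing.assert_allclose(bh_adjust(q), q)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5, np.nan])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, bad])


class TestFoldChange:
    def test_identity(self):
        assert fold_change(10, 10) == pytest.approx(0.0)

    def test_exact_doubling(self):
        assert fold_change(20, 10, pseudocount=1e-12) == pytest.approx(1.0)

    def test_double_zero_is_zero(self):
        assert fold_change(0, 0, pseudocount=0.5) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            fold_change(-1, 2)

    def test_antisymmetry(self):
        assert fold_change(8, 2, 1e-9) == pytest.approx(-fold_change(2, 8, 1e-9))


def region_sim(effects, seed=0, noise_sd=0.0, donor_sd=0.0, n_donors=6):
    base = SyntheticBulkSpec(
        n_genes=60, n_samples=1, planted=[("CXCR4", 0.9), ("PTGER4", 0.8)],
        noise_sd=noise_sd, seed=seed, dataset_id="reg",
    )
    spec = SyntheticRegionSpec(
        base=base, n_donors=n_donors, region_effects=effects, donor_sd=donor_sd
    )
    return simulate_paired_regions(spec)


class TestRegionDifferential:
    def test_planted_effect_flagged_wm_higher(self):
        matrix, samples, _ = region_sim([("CXCR4", 2.5)])
        res = region_differential(matrix, samples, genes=["CXCR4", "PTGER4"])
        assert res.table.loc["CXCR4", "direction"] == "WM_higher"
        assert res.table.loc["PTGER4", "direction"] == "none"

    def test_subthreshold_effect_not_called(self):
        matrix, samples, _ = region_sim([("CXCR4", 1.5)])
        res = region_differential(matrix, samples, genes=["CXCR4"])
        assert res.table.loc["CXCR4", "direction"] == "none"

    def test_identical_regions_give_zero_fold_changes(self):
        matrix, samples, _ = region_sim([])
        res = region_differential(matrix, samples)
        assert (res.table["direction"] == "none").all()
        np.testing.assert_allclose(res.table["log2_fold_change"], 0.0, atol=1e-12)

    def test_region_swap_negates_fold_change(self):
        matrix, samples, _ = region_sim([("CXCR4", 2.5)], donor_sd=0.1, noise_sd=0.01)
        res = region_differential(matrix, samples, genes=["CXCR4"])
        flipped = samples.table.copy()
        flipped["region"] = flipped["region"].map({"WM": "GM", "GM": "WM"})
        res2 = region_differential(
            matrix, type(samples)(flipped), genes=["CXCR4"]
        )
        assert res.table.loc["CXCR4", "log2_fold_change"] == pytest.approx(
            -res2.table.loc["CXCR4", "log2_fold_change"]
        )
        assert res.table.loc["CXCR4", "p"] == pytest.approx(
            res2.table.loc["CXCR4", "p"]
        )

    def test_paired_uses_signed_rank_with_enough_donors(self):
        matrix, samples, _ = region_sim([("CXCR4", 2.5)], donor_sd=0.1, noise_sd=0.01)
        res = region_differential(matrix, samples, genes=["CXCR4"], paired=True)
        assert res.table.loc["CXCR4", "method"].startswith("wilcoxon")

    def test_unmatched_donors_rejected_when_paired(self):
        matrix, samples, _ = region_sim([("CXCR4", 2.5)])
        broken = samples.table.copy()
        broken.loc[broken.index[0], "donor_id"] = "orphan"
        with pytest.raises(ValidationError, match="orphan"):
            region_differential(matrix, type(samples)(broken), paired=True)
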