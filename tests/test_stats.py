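import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from abcne import (
    StatsError,
    burrows_pair,
    expected_heterozygosity,
    fixation_index,
    mean_r2,
    multilocus_homozygosity,
    stats_vector,
)
from abcne.stats import _stats_from_dosage
from conftest import matrix_from_strings, random_matrix
from oracles import (
    oracle_burrows_r,
    oracle_expected_heterozygosity,
    oracle_fixation_index,
    oracle_mean_r2,
    oracle_multilocus_homozygosity,
)


class TestExpectedHeterozygosity:
    def test_half_frequency_locus(self):
        m = matrix_from_strings([["11"], ["12"], ["22"]])
        assert expected_heterozygosity(m) == pytest.approx(0.5)

    def test_monomorphic_locus_contributes_zero(self):
        m = matrix_from_strings([["11", "12"], ["11", "21"]])
        assert expected_heterozygosity(m) == pytest.approx(0.25)

    def test_two_locus_hand_arithmetic(self):
        # p = 0.5 and p = 0.1 -> (0.5 + 0.18)/2 = 0.34
        rows = [["12", "12"]] + [["12", "22"]] * 4
        m = matrix_from_strings(rows)
        assert expected_heterozygosity(m) == pytest.approx(0.34)

    def test_uncalled_locus_is_error(self):
        m = matrix_from_strings([["00", "12"], ["00", "12"]])
        with pytest.raises(StatsError, match="no called genotypes"):
            expected_heterozygosity(m)


class TestFixationIndex:
    def test_complete_heterozygote_excess(self):
        m = matrix_from_strings([["12"], ["12"], ["21"], ["12"]])
        assert fixation_index(m) == pytest.approx(-1.0)

    def test_exact_hwe_proportions(self, hwe_matrix):
        assert fixation_index(hwe_matrix) == pytest.approx(0.0)

    def test_no_heterozygotes(self):
        m = matrix_from_strings([["11"], ["11"], ["22"], ["22"]])
        assert fixation_index(m) == pytest.approx(1.0)

    def test_monomorphic_locus_is_error_by_default(self):
        m = matrix_from_strings([["11", "12"], ["11", "21"]])
        with pytest.raises(StatsError, match="MAF"):
            fixation_index(m)

    def test_skip_monomorphic_averages_remaining_loci(self):
        m = matrix_from_strings([["11", "12"], ["11", "21"]])
        assert fixation_index(m, skip_monomorphic=True) == pytest.approx(-1.0)


class TestMultilocusHomozygosity:
    def test_two_point_mean_and_variance(self):
        rows = [["11", "22", "11", "12"], ["12", "12", "11", "21"]]
        m = matrix_from_strings(rows)
        h_mean, h_var = multilocus_homozygosity(m)
        assert (h_mean, h_var) == (pytest.approx(2.0), pytest.approx(2.0))

    def test_all_heterozygous_is_degenerate_zero(self):
        m = matrix_from_strings([["12", "12"], ["21", "12"]])
        assert multilocus_homozygosity(m) == (0.0, 0.0)

    def test_equal_counts_give_zero_variance(self):
        m = matrix_from_strings([["11", "12"], ["22", "21"], ["11", "21"]])
        h_mean, h_var = multilocus_homozygosity(m)
        assert h_mean == pytest.approx(1.0)
        assert h_var == 0.0

    def test_single_individual_is_error(self):
        m = matrix_from_strings([["11", "12"]])
        with pytest.raises(StatsError, match="2 individuals"):
            multilocus_homozygosity(m)


class TestBurrowsPair:
    def test_perfect_coupling_gives_unit_r2(self):
        rows = [["11", "11"], ["22", "22"], ["11", "11"], ["22", "22"]]
        m = matrix_from_strings(rows)
        pair = burrows_pair(m, 0, 1)
        assert pair.usable
        assert pair.r_hat**2 == pytest.approx(1.0)
        assert pair.delta == pytest.approx(0.5)

    def test_monomorphic_locus_is_unusable(self):
        m = matrix_from_strings([["12", "11"], ["21", "11"]])
        assert not burrows_pair(m, 0, 1).usable

    def test_single_joint_individual_is_unusable(self):
        m = matrix_from_strings([["12", "12"], ["12", "00"], ["00", "12"]])
        assert not burrows_pair(m, 0, 1).usable

    def test_pairwise_deletion_matches_oracle(self, rng):
        m = random_matrix(rng, 8, 4, missing_rate=0.3)
        for i in range(4):
            for j in range(i + 1, 4):
                pair = burrows_pair(m, i, j)
                expected = oracle_burrows_r(m, i, j)
                if expected is None:
                    assert not pair.usable
                else:
                    assert pair.r_hat == pytest.approx(expected, abs=1e-12)


class TestMeanR2:
    def test_two_coupled_loci(self):
        rows = [["11", "11"], ["22", "22"], ["11", "11"], ["22", "22"]]
        assert mean_r2(matrix_from_strings(rows)) == pytest.approx(1.0)

    def test_no_usable_pair_is_error(self):
        m = matrix_from_strings([["12", "11"], ["21", "11"]])
        with pytest.raises(StatsError, match="usable"):
            mean_r2(m)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            m = random_matrix(rng, 6, 5, missing_rate=0.2)
            try:
                value = mean_r2(m)
            except StatsError:
                continue
            assert 0.0 <= value <= 1.0

    def test_independent_loci_null_scale(self, rng):
        # unlinked loci in an infinite population: E[r^2] ~ 1/S
        s = 100
        m = random_matrix(rng, s, 40)
        value = mean_r2(m)
        assert 0.5 / s < value < 2.0 / s

    def test_pair_subsampling_is_seeded_and_close(self, rng):
        m = random_matrix(rng, 30, 12)
        full = mean_r2(m)
        sub1 = mean_r2(m, max_pairs=30, rng=np.random.default_rng(5))
        sub2 = mean_r2(m, max_pairs=30, rng=np.random.default_rng(5))
        assert sub1 == sub2
        assert sub1 == pytest.approx(full, rel=0.8)

    def test_average_before_square_option(self):
        rows = [["11", "22"], ["22", "11"], ["11", "22"], ["22", "11"], ["12", "12"]]
        m = matrix_from_strings(rows)
        assert mean_r2(m, square_first=False) <= mean_r2(m)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("missing", [0.0, 0.25])
    def test_all_five_statistics_match_brute_force(self, seed, missing):
        rng = np.random.default_rng(seed)
        n_ind = int(rng.integers(4, 11))
        n_loci = int(rng.integers(2, 11))
        m = random_matrix(rng, n_ind, n_loci, missing_rate=missing)
        try:
            v = stats_vector(m, skip_monomorphic=True)
        except StatsError:
            assert oracle_mean_r2(m) is None
            return
        assert v.he == pytest.approx(oracle_expected_heterozygosity(m), abs=1e-12)
        assert v.fis == pytest.approx(
            oracle_fixation_index(m, skip_monomorphic=True), abs=1e-12
        )
        mean, var = oracle_multilocus_homozygosity(m)
        assert v.h_mean == pytest.approx(mean, abs=1e-12)
        assert v.h_var == pytest.approx(var, abs=1e-12)
        assert v.r2 == pytest.approx(oracle_mean_r2(m), abs=1e-12)

    def test_fast_dosage_path_matches_stats_vector(self, rng):
        for _ in range(5):
            m = random_matrix(rng, 12, 8)
            try:
                v = stats_vector(m, skip_monomorphic=True)
            except StatsError:
                continue
            fast = _stats_from_dosage(m.dosage())
            np.testing.assert_allclose(fast, v.as_array(), atol=1e-12)


class TestInvariances:
    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_permutation_and_label_swap_invariance(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 8, 6, missing_rate=0.1)
        try:
            base = stats_vector(m, skip_monomorphic=True).as_array()
        except StatsError:
            return
        perm_ind = m.take_individuals(rng.permutation(m.n_individuals))
        perm_loc = m.take_loci(rng.permutation(m.n_loci))
        np.testing.assert_allclose(
            stats_vector(perm_ind, skip_monomorphic=True).as_array(), base, atol=1e-12
        )
        np.testing.assert_allclose(
            stats_vector(perm_loc, skip_monomorphic=True).as_array(), base, atol=1e-12
        )
        # swap allele labels 1 <-> 2 at a random subset of loci
        swap = rng.random(m.n_loci) < 0.5
        calls = m.calls.copy()
        sub = calls[:, swap]
        sub[sub == 1] = 3
        sub[sub == 2] = 1
        sub[sub == 3] = 2
        calls[:, swap] = sub
        swapped = type(m)(calls)
        np.testing.assert_allclose(
            stats_vector(swapped, skip_monomorphic=True).as_array(), base, atol=1e-12
        )

    def test_homozygosity_heterozygosity_partition(self, rng):
        m = random_matrix(rng, 10, 7, missing_rate=0.2)
        h_mean, _ = multilocus_homozygosity(m)
        het_mean = (m.called & (m.dosage() == 1)).sum(axis=1).mean()
        called_mean = m.called.sum(axis=1).mean()
        assert h_mean + het_mean == pytest.approx(called_mean)
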