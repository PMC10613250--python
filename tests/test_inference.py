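"""Tests of the nonparametric resampling and cluster machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dyadsync import (
    InvalidArgumentError,
    PairingScheme,
    SimConfig,
    all_pairs_synchrony,
    circular_shift,
    circular_shift_null,
    cluster_permutation,
    cluster_permutation_subjectwise,
    fisher_z,
    fisher_z_inv,
    group_permutation,
    simulate_cohort,
    subject_bootstrap,
)
from dyadsync.evaluation import _all_pairs_dynamic, cluster_localization


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_maps_to_atanh(self):
        assert fisher_z(0.5) == pytest.approx(0.5493061443340549)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=-0.999, max_value=0.999))
    def test_round_trip(self, r):
        assert fisher_z_inv(fisher_z(r)) == pytest.approx(r, abs=1e-12)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.5])
    def test_domain_error(self, r):
        with pytest.raises(InvalidArgumentError):
            fisher_z(r)


def _pair_table(values):
    """Synchrony table over subjects s0..s{n-1} from a dict {(i,j): r}."""
    rows = [(f"s{i}", f"s{j}", "x", "joy", 1, r) for (i, j), r in values.items()]
    return pd.DataFrame(rows, columns=["subject_a", "subject_b", "pairing_scheme",
                                       "channel", "episode", "r"])


class TestSubjectBootstrap:
    def test_degenerate_equal_correlations_collapse_ci(self):
        c = 0.42
        table = _pair_table({(i, j): c for i in range(5) for j in range(i + 1, 5)})
        res = subject_bootstrap(table, n_boot=200, seed=0)
        assert res.ci_low == pytest.approx(c, abs=1e-12)
        assert res.ci_high == pytest.approx(c, abs=1e-12)
        assert res.observed_stat == pytest.approx(c, abs=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        table = _pair_table({(i, j): rng.uniform(-0.5, 0.5)
                             for i in range(6) for j in range(i + 1, 6)})
        a = subject_bootstrap(table, n_boot=300, seed=5)
        b = subject_bootstrap(table, n_boot=300, seed=5)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.null_distribution, b.null_distribution)

    def test_planted_coupling_detected(self, small_cohort):
        cohort, _, _ = small_cohort
        table = all_pairs_synchrony(cohort, "joy", subjects=cohort.dyad_subjects())
        res = subject_bootstrap(table, n_boot=500, seed=1)
        assert res.p_value < 0.05
        assert res.ci_low > 0

    def test_too_few_subjects(self):
        table = _pair_table({(0, 1): 0.3})
        with pytest.raises(InvalidArgumentError):
            subject_bootstrap(table)

    def test_p_value_never_zero(self, small_cohort):
        cohort, _, _ = small_cohort
        table = all_pairs_synchrony(cohort, "joy")
        res = subject_bootstrap(table, n_boot=200, seed=2)
        assert res.p_value >= 1 / 201


class TestCircularShift:
    def test_lag1_circular_autocorrelation_preserved_exactly(self):
        rng = np.random.default_rng(7)
        x = np.convolve(rng.standard_normal(500), np.hanning(9), "same")

        def circ_acf1(v):
            v = v - v.mean()
            return float(v @ np.roll(v, 1) / (v @ v))

        # the rotated series contains the identical multiset of lagged
        # products; only the floating-point summation order differs
        for offset in (1, 17, 250, 499):
            assert circ_acf1(circular_shift(x, offset)) == pytest.approx(
                circ_acf1(x), abs=1e-12
            )

    def test_shift_is_a_permutation_of_samples(self):
        x = np.arange(10.0)
        y = circular_shift(x, 3)
        assert sorted(y) == sorted(x)
        assert y[0] == x[3]


class TestCircularShiftNull:
    def test_stimulus_driven_cohort_exceeds_surrogates(self):
        cfg = SimConfig(n_dyads=0, n_alone=10, duration_s=240.0,
                        stimulus_coupling=0.8, dyad_coupling=0.0,
                        social_gain=1.0, seed=55)
        cohort, _ = simulate_cohort(cfg)
        res = circular_shift_null(cohort.series, "joy", n_surrogates=200, seed=3)
        assert res.observed_stat > np.percentile(res.null_distribution, 95)
        assert res.p_value < 0.05

    def test_determinism_and_p_floor(self, null_cohort):
        cohort, _, _ = null_cohort
        a = circular_shift_null(cohort.series, "joy", n_surrogates=150, seed=9)
        b = circular_shift_null(cohort.series, "joy", n_surrogates=150, seed=9)
        assert a.p_value == b.p_value and a.p_value > 0

    def test_argument_validation(self, null_cohort):
        cohort, _, _ = null_cohort
        with pytest.raises(InvalidArgumentError):
            circular_shift_null(cohort.series, "joy", n_surrogates=50)
        short = {k: v for k, v in list(cohort.series.items())[:3]}
        import dataclasses

        clipped = {
            k: dataclasses.replace(s, values=s.values[:50],
                                   missing_mask=s.missing_mask[:50])
            for k, s in short.items()
        }
        with pytest.raises(InvalidArgumentError):
            circular_shift_null(clipped, "joy", n_surrogates=150)


class TestGroupPermutation:
    def test_planted_group_difference_detected(self):
        cfg = SimConfig(n_dyads=8, n_alone=10, duration_s=300.0,
                        dyad_coupling=0.8, seed=66)
        cohort, _ = simulate_cohort(cfg)
        table = all_pairs_synchrony(cohort, "joy")
        res = group_permutation(
            table,
            PairingScheme.true_dyads(cohort),
            PairingScheme.alone_all_pairs(cohort),
            n_perm=500,
            seed=4,
        )
        assert res.observed_stat > 0
        assert res.p_value < 0.05

    def test_deterministic_given_seed(self, null_cohort):
        cohort, _, _ = null_cohort
        table = all_pairs_synchrony(cohort, "joy")
        args = (table, PairingScheme.true_dyads(cohort),
                PairingScheme.alone_all_pairs(cohort))
        assert (group_permutation(*args, n_perm=200, seed=8).p_value
                == group_permutation(*args, n_perm=200, seed=8).p_value)

    def test_null_p_values_are_uniform(self, null_permutation_pvalues):
        # identical-population groups: Kolmogorov-Smirnov test against
        # Uniform(0, 1] must not reject across 500 independent cohorts
        from scipy.stats import kstest

        stat = kstest(null_permutation_pvalues, "uniform")
        assert stat.pvalue > 0.01

    def test_overlapping_groups_rejected(self, null_cohort):
        cohort, _, _ = null_cohort
        table = all_pairs_synchrony(cohort, "joy")
        scheme = PairingScheme.true_dyads(cohort)
        with pytest.raises(InvalidArgumentError):
            group_permutation(table, scheme, scheme, n_perm=100, seed=0)


class TestClusterPermutation:
    def test_no_suprathreshold_samples_gives_empty_result(self):
        rng = np.random.default_rng(10)
        base = rng.uniform(-0.05, 0.05, size=(1, 100))
        d1 = np.repeat(base, 8, axis=0) + rng.normal(0, 1e-3, (8, 100))
        d2 = np.repeat(base, 8, axis=0) + rng.normal(0, 1e-3, (8, 100))
        res = cluster_permutation(d1, d2, n_perm=100, seed=1,
                                  cluster_alpha=1e-9)
        assert res.clusters == []

    def test_clusters_ordered_and_non_overlapping(self):
        rng = np.random.default_rng(11)
        d1 = rng.uniform(-0.3, 0.3, (10, 200))
        d1[:, 50:70] += 0.5
        d1[:, 120:140] -= 0.5
        d2 = rng.uniform(-0.3, 0.3, (10, 200))
        res = cluster_permutation(d1, d2, n_perm=100, seed=2)
        starts = [c.start_s for c in res.clusters]
        assert starts == sorted(starts)
        for first, second in zip(res.clusters, res.clusters[1:]):
            assert first.end_s < second.start_s

    def test_mismatched_time_grids_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cluster_permutation(np.zeros((4, 50)), np.zeros((4, 60)))

    def test_planted_epoch_detected_subjectwise(self):
        assert cluster_localization(n_runs=3, seed=77, n_perm=200) == 1.0

    def test_deterministic_given_seed(self, null_cohort):
        cohort, _, _ = null_cohort
        subjects = cohort.alone_subjects()
        dyn, pairs = _all_pairs_dynamic(cohort, subjects, "joy")
        kwargs = dict(n_perm=100, seed=3)
        r1 = cluster_permutation_subjectwise(dyn, pairs, subjects[:4],
                                             subjects[4:], **kwargs)
        r2 = cluster_permutation_subjectwise(dyn, pairs, subjects[:4],
                                             subjects[4:], **kwargs)
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]
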