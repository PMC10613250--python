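"""Tests of pair counting and global/dynamic/lagged synchrony."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dyadsync import (
    InvalidArgumentError,
    PairingScheme,
    SimConfig,
    UndefinedCorrelationError,
    crosscorr_offset,
    dynamic_synchrony,
    global_synchrony,
    group_synchrony,
    pair_count,
    pseudo_pair_count,
    simulate_cohort,
)
from conftest import make_series


class TestPairCounts:
    @pytest.mark.parametrize("n,expected", [(21, 210), (2, 1), (56, 1540), (0, 0)])
    def test_pair_count_closed_form(self, n, expected):
        assert pair_count(n) == expected

    @pytest.mark.parametrize(
        "n,n_true,expected", [(56, 28, 1512), (4, 2, 4), (2, 1, 0)]
    )
    def test_pseudo_pair_count(self, n, n_true, expected):
        assert pseudo_pair_count(n, n_true) == expected

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            pair_count(-1)
        with pytest.raises(InvalidArgumentError):
            pseudo_pair_count(5, 2)  # odd group size
        with pytest.raises(InvalidArgumentError):
            pseudo_pair_count(4, 3)  # more true pairs than possible

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=200))
    def test_pair_count_matches_enumeration(self, n):
        assert pair_count(n) == len(list(combinations(range(n), 2)))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=1, max_value=100))
    def test_scheme_partition_counts_are_additive(self, n_dyads):
        n = 2 * n_dyads
        assert pair_count(n) == pseudo_pair_count(n, n_dyads) + n_dyads


class TestPairingScheme:
    def test_schemes_partition_dyad_group(self, small_cohort):
        cohort, _, _ = small_cohort
        true = set(map(frozenset, PairingScheme.true_dyads(cohort).pairs))
        pseudo = set(map(frozenset, PairingScheme.pseudo_dyads(cohort).pairs))
        everyone = set(
            map(frozenset, combinations(cohort.dyad_subjects(), 2))
        )
        assert true | pseudo == everyone
        assert not true & pseudo

    def test_self_pairs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            PairingScheme("true_dyads", [("a", "a")])


class TestGlobalSynchrony:
    def test_identical_series_correlate_perfectly(self):
        x = np.sin(np.arange(100) / 5.0)
        assert global_synchrony(make_series(x), make_series(x), "ch0") == 1.0

    def test_negated_series(self):
        x = np.sin(np.arange(100) / 5.0)
        assert global_synchrony(make_series(x), make_series(-x), "ch0") == -1.0

    def test_independent_series_near_zero(self):
        # null-distribution oracle: for T=10,000 the sampling sd of r is
        # about 0.01, so |r| < 0.05 is a 5-sigma event
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            a = make_series(rng.standard_normal(10_000))
            b = make_series(rng.standard_normal(10_000))
            hits += abs(global_synchrony(a, b, "ch0")) < 0.05
        assert hits >= 99

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            global_synchrony(
                make_series(np.ones(50)), make_series(np.arange(50.0)), "ch0"
            )

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(200), rng.standard_normal(200)
        a, b = make_series(x), make_series(y)
        r = global_synchrony(a, b, "ch0")
        assert global_synchrony(b, a, "ch0") == r
        scaled = make_series(3.5 * y + 11.0)
        assert global_synchrony(a, scaled, "ch0") == pytest.approx(r, abs=1e-12)

    def test_pairwise_deletion_over_joint_mask(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        y = x + 0.1 * rng.standard_normal(100)
        mask_a = np.zeros(100, bool)
        mask_a[:10] = True
        a_vals = x.copy()
        a_vals[:10] = 1e9  # junk under the mask must not matter
        a = make_series(a_vals, mask=mask_a)
        b = make_series(y)
        expected = np.corrcoef(x[10:], y[10:])[0, 1]
        assert global_synchrony(a, b, "ch0") == pytest.approx(expected, abs=1e-12)

    def test_too_few_joint_samples(self):
        a = make_series(np.arange(40.0), mask=np.arange(40) < 20)
        b = make_series(np.arange(40.0), mask=np.arange(40) >= 25)
        with pytest.raises(InvalidArgumentError):
            global_synchrony(a, b, "ch0")


class TestDynamicSynchrony:
    def test_identical_series_give_unit_windows(self):
        x = np.sin(np.arange(120) / 3.0) + 0.01 * np.arange(120)
        out = dynamic_synchrony(make_series(x), make_series(x), "ch0")
        np.testing.assert_allclose(out["r"], 1.0, atol=1e-9)

    def test_constant_window_is_masked(self):
        x = np.concatenate([np.zeros(60), np.sin(np.arange(60) / 3.0)])
        y = np.sin(np.arange(120) / 4.0)
        out = dynamic_synchrony(make_series(x), make_series(y), "ch0")
        assert np.isnan(out["r"].iloc[10])
        assert np.isfinite(out["r"].iloc[90])

    def test_shared_epoch_raises_windowed_synchrony(self):
        # construction oracle: a common sine injected only during
        # [200, 260] s must lift the windowed correlation inside the epoch
        rng = np.random.default_rng(3)
        t = np.arange(400.0)
        burst = np.where((t >= 200) & (t <= 260), np.sin(2 * np.pi * t / 10), 0.0)
        a = make_series(burst + rng.standard_normal(400))
        b = make_series(burst + rng.standard_normal(400))
        out = dynamic_synchrony(a, b, "ch0")
        inside = out[(out["time_s"] >= 200) & (out["time_s"] <= 260)]["r"]
        outside = out[(out["time_s"] < 170) | (out["time_s"] > 290)]["r"]
        assert inside.mean() > outside.mean()

    def test_full_length_window_matches_global(self):
        # windows are centred with truncated edges, so the window centred
        # at the series midpoint covers every sample
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal(100), rng.standard_normal(100)
        a, b = make_series(x), make_series(y)
        out = dynamic_synchrony(a, b, "ch0", window_s=100.0)
        mid = out.loc[out["time_s"] == 50.0, "r"].iloc[0]
        assert mid == pytest.approx(global_synchrony(a, b, "ch0"), abs=1e-9)

    def test_invalid_step(self):
        a = make_series(np.arange(100.0))
        with pytest.raises(InvalidArgumentError):
            dynamic_synchrony(a, a, "ch0", step_s=0)

    def test_output_covers_every_step(self):
        a = make_series(np.sin(np.arange(150) / 3.0))
        out = dynamic_synchrony(a, a, "ch0")
        assert len(out) == 150
        np.testing.assert_array_equal(out["time_s"], np.arange(150.0))


class TestCrosscorrOffset:
    def test_constructed_delay_is_recovered(self):
        rng = np.random.default_rng(5)
        fs = 10.0
        x = np.convolve(rng.standard_normal(3000), np.hanning(21), "same")
        delay = 10  # 1.0 s at 10 Hz
        y = np.roll(x, delay)
        a = make_series(x, fs_hz=fs)
        b = make_series(y, fs_hz=fs)
        _, best = crosscorr_offset(a, b, "ch0")
        assert best == pytest.approx(1.0)

    def test_no_delay_for_identical_series(self):
        x = np.sin(np.arange(0, 100, 0.1))
        a = make_series(x, fs_hz=10.0)
        _, best = crosscorr_offset(a, a, "ch0")
        assert best == 0.0

    def test_independent_noise_profile_stays_small(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(20):
            a = make_series(rng.standard_normal(5000), fs_hz=10.0)
            b = make_series(rng.standard_normal(5000), fs_hz=10.0)
            profile, _ = crosscorr_offset(a, b, "ch0")
            hits += profile["r"].abs().max() < 0.1
        assert hits >= 19

    def test_short_series_rejected(self):
        a = make_series(np.arange(40.0), fs_hz=10.0)
        with pytest.raises(InvalidArgumentError):
            crosscorr_offset(a, a, "ch0", max_lag_s=3.0)

    def test_rate_too_low_for_step(self):
        a = make_series(np.arange(100.0), fs_hz=1.0)
        with pytest.raises(InvalidArgumentError):
            crosscorr_offset(a, a, "ch0", step_s=0.1)


class TestGroupSynchrony:
    def test_row_counts_match_pair_formulas(self):
        cfg = SimConfig(n_dyads=28, n_alone=21, duration_s=120.0, seed=40)
        cohort, _ = simulate_cohort(cfg)
        alone = group_synchrony(cohort, PairingScheme.alone_all_pairs(cohort), "joy")
        dyads = group_synchrony(cohort, PairingScheme.true_dyads(cohort), "joy")
        pseudo = group_synchrony(cohort, PairingScheme.pseudo_dyads(cohort), "joy")
        assert len(alone) == 210
        assert len(dyads) == 28
        assert len(pseudo) == 1512

    def test_excluded_subject_in_scheme_rejected(self, small_cohort):
        cohort, _, _ = small_cohort
        scheme = PairingScheme.true_dyads(cohort)
        victim = scheme.pairs[0][0]
        with pytest.raises(InvalidArgumentError, match=victim):
            group_synchrony(cohort, scheme, "joy", excluded=[victim])

    def test_r_values_within_bounds(self, small_cohort):
        cohort, _, _ = small_cohort
        table = group_synchrony(cohort, PairingScheme.pseudo_dyads(cohort), "joy")
        assert table["r"].between(-1, 1).all()
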