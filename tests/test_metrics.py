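"""Entrainment metrics: examples, identities and null behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tacsim.errors import InvalidArgument, UndefinedStatistic
from tacsim.metrics import (
    EntrainmentSummary,
    aggregate_phases,
    cartesian_to_polar,
    circ_sd,
    epoch_xcorr,
    linfit,
    normalized_firing_rate,
    percent_change,
    phase_coherence,
    plv,
    polar_histogram,
    polar_to_cartesian,
    ppc,
    ppc_from_plv,
    preferred_phase,
    rayleigh_test,
    sliding_phase_coherence,
    summarize_phases,
    wilcoxon_signed_rank,
    zero_lag_xcorr,
)

angles = st.lists(st.floats(0, 359.999), min_size=2, max_size=60)


def brute_force_ppc(phases_deg):
    """O(n^2) pairwise mean cosine, the defining double sum."""
    r = np.deg2rad(np.asarray(phases_deg))
    n = r.size
    total = 0.0
    for j in range(n - 1):
        for k in range(j + 1, n):
            total += np.cos(r[j] - r[k])
    return 2.0 * total / (n * (n - 1))


class TestZeroLagXcorr:
    def test_identical_signals_give_one(self):
        x = np.sin(np.linspace(0, 20, 500))
        assert zero_lag_xcorr(x, x) == pytest.approx(1.0)

    def test_inverted_signals_give_minus_one(self):
        x = np.sin(np.linspace(0, 20, 500))
        assert zero_lag_xcorr(x, -x) == pytest.approx(-1.0)

    def test_orthogonal_sinusoids_give_zero(self):
        t = np.linspace(0, 2 * np.pi, 10_000, endpoint=False)
        assert zero_lag_xcorr(np.sin(t), np.cos(t)) == pytest.approx(
            0.0, abs=1e-10)

    def test_zero_variance_raises_not_silent_zero(self):
        with pytest.raises(UndefinedStatistic):
            zero_lag_xcorr(np.ones(10), np.arange(10.0))

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=100), rng.normal(size=100)
        assert zero_lag_xcorr(x, y) == pytest.approx(zero_lag_xcorr(y, x))


class TestEpochXcorr:
    def test_identical_traces_give_unit_r_everywhere(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=15_000)
        out = epoch_xcorr([base.copy() for _ in range(4)])
        assert len(out) == 6  # C(4,2)
        for ec in out:
            assert np.allclose(ec.r, 1.0)

    def test_pair_count_is_n_choose_two(self):
        rng = np.random.default_rng(2)
        traces = [rng.normal(size=15_000) for _ in range(3)]
        assert len(epoch_xcorr(traces)) == 3

    def test_independent_noise_has_near_zero_median(self):
        rng = np.random.default_rng(3)
        traces = [rng.normal(size=15_000) for _ in range(8)]
        rs = np.concatenate([ec.r for ec in epoch_xcorr(traces)])
        assert abs(np.median(rs)) < 0.05

    def test_short_trace_rejected(self):
        with pytest.raises(InvalidArgument):
            epoch_xcorr([np.zeros(100), np.zeros(100)])


class TestPhaseCoherence:
    def test_equal_series_give_one(self):
        ph = np.linspace(0, 3600, 2500) % 360
        assert phase_coherence(ph, ph) == pytest.approx(1.0)

    def test_constant_offset_still_gives_one(self):
        ph = np.linspace(0, 3600, 2500) % 360
        assert phase_coherence(ph, (ph + 37.0) % 360) == pytest.approx(1.0)

    def test_independent_uniform_series_near_zero(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 360, 2500)
        b = rng.uniform(0, 360, 2500)
        assert phase_coherence(a, b) < 0.05

    def test_null_decays_as_inverse_sqrt_n(self):
        """Monte-Carlo slope of log-mean-coherence vs log-n within 10% of -1/2."""
        rng = np.random.default_rng(5)
        ns = np.array([100, 400, 1600, 6400])
        means = []
        for n in ns:
            vals = [phase_coherence(rng.uniform(0, 360, n),
                                    rng.uniform(0, 360, n))
                    for _ in range(60)]
            means.append(np.mean(vals))
        slope, _, _ = linfit(np.log(ns), np.log(means))
        assert slope == pytest.approx(-0.5, rel=0.10)

    def test_sliding_variant_returns_one_value_per_step(self):
        ph = np.linspace(0, 36000, 5000) % 360
        starts, coh = sliding_phase_coherence(ph, ph, dt_ms=1.0,
                                              window_ms=2500.0, step_ms=100.0)
        assert starts.size == coh.size == (5000 - 2500) // 100 + 1
        assert np.allclose(coh, 1.0)


class TestPlvPpc:
    def test_all_equal_phases_lock_fully(self):
        assert plv([42.0] * 7) == pytest.approx(1.0)
        assert ppc([42.0] * 7) == pytest.approx(1.0)

    def test_four_cardinal_phases_cancel(self):
        sample = [0.0, 90.0, 180.0, 270.0]
        assert plv(sample) == pytest.approx(0.0, abs=1e-12)
        assert ppc(sample) == pytest.approx(-1.0 / 3.0, abs=1e-12)

    def test_plv_one_third_example(self):
        assert plv([0.0, 0.0, 180.0]) == pytest.approx(1.0 / 3.0)

    def test_antipodal_pair_has_ppc_minus_one(self):
        assert ppc([0.0, 180.0]) == pytest.approx(-1.0)

    def test_plv_invariant_under_rotation(self):
        rng = np.random.default_rng(6)
        ph = rng.uniform(0, 360, 200)
        for rot in (13.0, 90.0, 211.5):
            assert plv((ph + rot) % 360) == pytest.approx(plv(ph), abs=1e-12)

    @given(angles)
    @settings(max_examples=60, deadline=None)
    def test_ppc_identity_with_plv_squared(self, ph):
        """(n PLV^2 - 1)/(n - 1) equals the pairwise mean cosine exactly."""
        assert ppc(ph) == pytest.approx(
            ppc_from_plv(plv(ph), len(ph)), abs=1e-12)

    def test_ppc_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(7)
        ph = rng.uniform(0, 360, 40)
        assert ppc(ph) == pytest.approx(brute_force_ppc(ph), abs=1e-12)

    def test_ppc_chunked_path_matches_identity_at_large_n(self):
        rng = np.random.default_rng(8)
        ph = rng.vonmises(0.3, 1.2, size=5000)
        ph = np.rad2deg(ph) % 360
        assert ppc(ph) == pytest.approx(ppc_from_plv(plv(ph), ph.size),
                                        abs=1e-10)

    def test_plv_monotone_in_concentration(self):
        from tacsim.synthetic import sample_von_mises
        vals = [plv(sample_von_mises(0, k, 40_000, seed=3))
                for k in (0.5, 1.0, 2.0, 4.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_empty_or_tiny_samples_rejected(self):
        with pytest.raises(InvalidArgument):
            plv([])
        with pytest.raises(InvalidArgument):
            ppc([10.0])


class TestCircularDescriptives:
    def test_mean_of_symmetric_pair_is_zero(self):
        assert preferred_phase([10.0, 350.0]) == pytest.approx(0.0, abs=1e-9)

    def test_mean_wraps_correctly(self):
        assert preferred_phase([370.0 % 360, 10.0]) == pytest.approx(10.0)

    def test_identical_phases_have_zero_sd(self):
        assert circ_sd([33.0, 33.0, 33.0]) == pytest.approx(0.0, abs=1e-9)

    def test_sd_formula_sqrt_minus_two_log_r(self):
        rng = np.random.default_rng(9)
        ph = np.rad2deg(rng.vonmises(0, 2.0, 1000)) % 360
        r = plv(ph)
        assert circ_sd(ph) == pytest.approx(
            np.rad2deg(np.sqrt(-2 * np.log(r))), rel=1e-9)

    def test_undefined_mean_raises(self):
        with pytest.raises(UndefinedStatistic):
            preferred_phase([0.0, 90.0, 180.0, 270.0])

    def test_von_mises_mean_recovered_within_one_degree(self):
        from tacsim.synthetic import sample_von_mises
        s = sample_von_mises(200.0, 2.0, 100_000, seed=10)
        assert preferred_phase(s) == pytest.approx(200.0, abs=1.0)


class TestRayleigh:
    def test_uniform_sample_is_not_significant(self):
        rng = np.random.default_rng(11)
        assert rayleigh_test(rng.uniform(0, 360, 10_000)) > 0.05

    def test_z_of_25_is_overwhelming(self):
        # n = 100 at PLV = 0.5 -> Z = 25
        from tacsim.synthetic import sample_von_mises
        ph = np.rad2deg(np.zeros(50)).tolist() + list(
            np.linspace(0, 359, 50))  # engineered PLV ~ 0.5
        z = 100 * plv(ph) ** 2
        assert z > 20
        assert rayleigh_test(ph) < 1e-9

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        ph = rng.uniform(0, 360, 500)
        shuffled = rng.permutation(ph)
        assert rayleigh_test(ph) == pytest.approx(rayleigh_test(shuffled))

    def test_agrees_with_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(13)
        for kappa in (0.0, 0.5, 2.0):
            ph = np.rad2deg(rng.vonmises(0, kappa, 300)) % 360
            z, p_ref = pingouin.circ_rayleigh(np.deg2rad(ph))
            assert rayleigh_test(ph) == pytest.approx(p_ref, rel=1e-4, abs=1e-12)


class TestWilcoxon:
    def test_identical_samples_are_degenerate(self):
        with pytest.raises(UndefinedStatistic):
            wilcoxon_signed_rank(np.ones(10), np.ones(10))

    def test_large_uniform_shift_is_significant(self):
        rng = np.random.default_rng(14)
        a = rng.normal(size=20)
        assert wilcoxon_signed_rank(a, a + 50.0) < 0.005

    def test_two_sided_p_symmetric_in_argument_order(self):
        rng = np.random.default_rng(15)
        a = rng.normal(size=25)
        b = a + rng.normal(size=25)
        assert wilcoxon_signed_rank(a, b) == pytest.approx(
            wilcoxon_signed_rank(b, a))


class TestRatesAndRegressions:
    def test_unchanged_rate_maps_to_one(self):
        assert normalized_firing_rate([10.0], 10.0)[0] == pytest.approx(1.0)

    def test_half_percent_change_example(self):
        ratio = normalized_firing_rate([10.05], 10.0)
        assert percent_change(ratio)[0] == pytest.approx(0.5)

    def test_scale_invariance(self):
        r1 = normalized_firing_rate([8.0, 12.0], 10.0)
        r2 = normalized_firing_rate([16.0, 24.0], 20.0)
        assert np.allclose(r1, r2)

    def test_zero_baseline_rejected(self):
        with pytest.raises(InvalidArgument):
            normalized_firing_rate([1.0], 0.0)

    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        slope, intercept, r2 = linfit(x, 2 * x + 1)
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_uncorrelated_noise_has_low_r_squared(self):
        rng = np.random.default_rng(16)
        _, _, r2 = linfit(np.arange(2000.0), rng.normal(size=2000))
        assert r2 < 0.01

    def test_constant_x_rejected(self):
        with pytest.raises(InvalidArgument):
            linfit(np.ones(5), np.arange(5.0))

    def test_plv_squared_vs_ppc_regression_identity(self):
        """Over von Mises samples, PLV^2 = PPC + (1 - PPC)/n: slope near 1,
        intercept of order 1/n."""
        from tacsim.synthetic import sample_von_mises
        xs, ys = [], []
        for i, k in enumerate((0.5, 1.0, 2.0, 4.0)):
            s = sample_von_mises(0, k, 1000, seed=20 + i)
            xs.append(ppc(s))
            ys.append(plv(s) ** 2)
        slope, intercept, r2 = linfit(np.array(xs), np.array(ys))
        assert slope == pytest.approx(1.0, abs=0.01)
        assert abs(intercept) < 0.005
        assert r2 > 0.999


class TestPolar:
    def test_axis_aligned_conversions(self):
        s0 = EntrainmentSummary("c", 1.0, "alpha", 1.0, 1.0, 0.0, 0.0, 10, 0.0)
        s90 = EntrainmentSummary("c", 1.0, "alpha", 0.5, 0.25, 90.0, 0.0, 10, 0.0)
        _, xs, ys = polar_to_cartesian([s0, s90])
        assert xs[0] == pytest.approx(1.0) and ys[0] == pytest.approx(0.0)
        assert xs[1] == pytest.approx(0.0, abs=1e-12) and ys[1] == pytest.approx(0.5)

    @given(st.floats(0, 359.99), st.floats(1e-6, 1.0))
    @settings(max_examples=80, deadline=None)
    def test_round_trip_is_exact(self, theta, r):
        s = EntrainmentSummary("c", 1.0, "alpha", r, r * r, theta, 0.0, 10, 0.0)
        _, xs, ys = polar_to_cartesian([s])
        theta2, r2 = cartesian_to_polar(xs[0], ys[0])
        assert r2 == pytest.approx(r, abs=1e-12)
        assert min(abs(theta2 - theta), 360 - abs(theta2 - theta)) < 1e-9

    def test_undefined_phase_skipped(self):
        bad = EntrainmentSummary("c", 1.0, "alpha", 0.0, 0.0, float("nan"),
                                 0.0, 10, 1.0)
        amps, xs, ys = polar_to_cartesian([bad])
        assert xs.size == 0


class TestPolarHistogram:
    def test_point_mass_fills_one_bin(self):
        edges, counts = polar_histogram([0.0] * 50, 8)
        assert counts[0] == 50 and counts[1:].sum() == 0

    def test_uniform_sample_spreads_evenly(self):
        rng = np.random.default_rng(17)
        ph = rng.uniform(0, 360, 100_000)
        _, counts = polar_histogram(ph, 8)
        expect = 100_000 / 8
        assert np.all(np.abs(counts - expect) < 3 * np.sqrt(expect) + 1)

    def test_counts_conserved_across_bin_choices(self):
        rng = np.random.default_rng(18)
        ph = rng.uniform(0, 360, 777)
        for nb in (4, 12, 36):
            assert polar_histogram(ph, nb)[1].sum() == 777

    def test_invalid_bins_rejected(self):
        with pytest.raises(InvalidArgument):
            polar_histogram([1.0], 0)


class TestAggregation:
    def test_concatenation_equals_weighted_resultant(self):
        """Pooling trials then computing PLV equals combining per-trial
        resultant vectors weighted by their spike counts."""
        rng = np.random.default_rng(19)
        trials = [np.rad2deg(rng.vonmises(1.0, 1.5, n)) % 360
                  for n in (37, 120, 64)]
        pooled = aggregate_phases(trials)
        direct = plv(pooled)
        z = sum(np.exp(1j * np.deg2rad(t)).sum() for t in trials)
        weighted = abs(z) / sum(len(t) for t in trials)
        assert direct == pytest.approx(weighted, abs=1e-12)

    def test_summary_fields_are_consistent(self):
        rng = np.random.default_rng(20)
        ph = np.rad2deg(rng.vonmises(2.0, 3.0, 500)) % 360
        s = summarize_phases(ph, cell="L5_PC", amplitude_ma=1.0, band="alpha")
        assert s.n_spikes == 500
        assert 0 <= s.plv <= 1
        assert s.ppc == pytest.approx(ppc_from_plv(s.plv, 500), abs=1e-12)
        assert s.rayleigh_p < 0.01
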