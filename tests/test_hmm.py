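"""Two-state HMM trajectory analysis and the equilibrium-force scan."""

import numpy as np
import pytest

from snarefold.hmm import (
    equilibrium_force_scan,
    extension_histogram_fit,
    fit_two_state_hmm,
    mean_filter,
)
from snarefold.simulate import Trajectory, simulate_constant_separation


def _square_wave_trajectory(
    period_s=0.02, duration=2.0, gap=8.0, noise=0.0, seed=0, dt=1e-4, offset=0.0
):
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration / dt)) * dt
    states = ((t // (period_s / 2)) % 2).astype(int)
    x = offset + gap * states + rng.normal(0, noise, len(t))
    force = 16.0 - 0.1 * (x - offset)
    return Trajectory(time=t, extension=x, force=force, metadata={"separation": 900.0}), states


class TestMeanFilter:
    def test_single_sample_window_is_identity(self):
        x = np.random.default_rng(1).normal(size=100)
        assert np.array_equal(mean_filter(x, 1e-4, 1e-4), x)

    def test_constant_trace_unchanged(self):
        x = np.full(500, 3.7)
        assert np.allclose(mean_filter(x, 5e-3, 1e-4), 3.7)

    def test_step_becomes_linear_ramp_of_window_width(self):
        """Direct convolution oracle: a unit step filtered with a w-sample
        boxcar ramps linearly over w samples."""
        x = np.concatenate([np.zeros(100), np.ones(100)])
        w = 10
        y = mean_filter(x, w * 1e-4, 1e-4)
        oracle = np.convolve(x, np.ones(w) / w, mode="same")
        interior = slice(w, len(x) - w)
        assert np.allclose(y[interior], oracle[interior])
        ramp = y[95:105]
        assert np.all(np.diff(ramp) >= 0)
        assert np.allclose(np.diff(ramp)[1:-1], 1.0 / w)

    def test_window_below_sampling_interval_rejected(self):
        with pytest.raises(ValueError):
            mean_filter(np.zeros(10), 1e-5, 1e-4)


class TestTwoStateHMM:
    def test_noise_free_square_wave_recovered_exactly(self):
        """Alternating square wave: exact state means and dwell rates."""
        traj, states = _square_wave_trajectory(period_s=0.02, duration=2.0, gap=8.0)
        r = fit_two_state_hmm(traj, filter_window=1e-4)  # no filtering
        assert r.state_means == pytest.approx([0.0, 8.0], abs=1e-9)
        assert np.array_equal(r.idealized_path, states)
        # 100 dwells of 10 ms per state -> both rates 100 1/s
        assert r.k_fold == pytest.approx(100.0, rel=0.02)
        assert r.k_unfold == pytest.approx(100.0, rel=0.02)
        assert r.p_unfold == pytest.approx(0.5, abs=0.01)

    def test_rates_recovered_within_15_percent(self, neuronal):
        """Simulator ground truth: 10 s at the equilibrium separation where
        both rates are ~100 1/s."""
        sys = neuronal.ctd
        traj = simulate_constant_separation(sys, sys.separation_half, 10.0, seed=101)
        r = fit_two_state_hmm(traj)
        assert r.k_fold == pytest.approx(traj.metadata["true_k_fold"], rel=0.15)
        assert r.k_unfold == pytest.approx(traj.metadata["true_k_unfold"], rel=0.15)

    def test_probability_at_equilibrium_separation(self, neuronal):
        """Equal system energies: p = 0.5 within 3 SE."""
        sys = neuronal.ctd
        traj = simulate_constant_separation(sys, sys.separation_half, 10.0, seed=103)
        r = fit_two_state_hmm(traj)
        se = 0.5 / np.sqrt(max(r.n_transitions, 1))
        assert abs(r.p_unfold - 0.5) < 3 * se

    def test_rates_invariant_to_extension_offset(self):
        a, _ = _square_wave_trajectory(noise=1.5, seed=7)
        b, _ = _square_wave_trajectory(noise=1.5, seed=7, offset=250.0)
        ra, rb = fit_two_state_hmm(a), fit_two_state_hmm(b)
        assert ra.k_fold == pytest.approx(rb.k_fold, rel=1e-9)
        assert ra.k_unfold == pytest.approx(rb.k_unfold, rel=1e-9)
        assert rb.state_means - ra.state_means == pytest.approx([250.0, 250.0], abs=1e-6)

    def test_degenerate_fit_flagged(self):
        rng = np.random.default_rng(5)
        t = np.arange(20000) * 1e-4
        x = rng.normal(0, 0.05, len(t))  # single state, SD far below 0.5 nm
        traj = Trajectory(time=t, extension=x, force=np.full_like(t, 10.0))
        r = fit_two_state_hmm(traj)
        assert "degenerate" in r.flags

    def test_requires_one_second_of_data(self):
        t = np.arange(100) * 1e-4
        traj = Trajectory(time=t, extension=np.zeros(100), force=np.zeros(100))
        with pytest.raises(ValueError):
            fit_two_state_hmm(traj)

    def test_detailed_balance_recovered(self, neuronal):
        """p/(1-p) from the idealized path matches the Boltzmann factor of
        the preset landscape within 3 SE on the logit scale."""
        from snarefold.landscape import landscape_predictions, params_of_system

        sys = neuronal.ctd
        d = sys.separation_half - 2.5
        traj = simulate_constant_separation(sys, d, 10.0, seed=107)
        r = fit_two_state_hmm(traj)
        p_model = landscape_predictions(params_of_system(sys), sys, [d])["p"].iloc[0]
        logit = lambda p: np.log(p / (1 - p))
        se_logit = 1.0 / np.sqrt(r.n_transitions * r.p_unfold * (1 - r.p_unfold))
        assert abs(logit(r.p_unfold) - logit(p_model)) < 3 * se_logit


class TestHistogramFit:
    def test_two_delta_clusters_weights_equal_occupancies(self):
        x = np.concatenate([np.full(3000, 0.0), np.full(7000, 8.0)])
        x = x + np.random.default_rng(3).normal(0, 0.3, len(x))
        fit = extension_histogram_fit(x, bins=60)
        assert fit.means == pytest.approx([0.0, 8.0], abs=0.1)
        assert fit.weights == pytest.approx([0.3, 0.7], abs=0.03)

    def test_agrees_with_hmm_state_means(self, neuronal):
        sys = neuronal.ctd
        traj = simulate_constant_separation(sys, sys.separation_half, 5.0, seed=109)
        r = fit_two_state_hmm(traj)
        filt = mean_filter(traj.extension, 1e-3, traj.sampling_interval)
        fit = extension_histogram_fit(filt)
        assert abs(fit.means[0] - r.state_means[0]) < 1.0
        assert abs(fit.means[1] - r.state_means[1]) < 1.0

    def test_unimodal_input_flagged(self):
        x = np.random.default_rng(11).normal(5.0, 1.0, 20000)
        fit = extension_histogram_fit(x)
        assert "unimodal" in fit.flags


class TestEquilibriumForceScan:
    def test_neuronal_scan_recovers_published_force(self, neuronal_ctd_scan, neuronal):
        t = neuronal.ctd.table
        assert neuronal_ctd_scan.f_half == pytest.approx(t.f_half, abs=t.f_half_sd)
        assert neuronal_ctd_scan.delta_x_half == pytest.approx(t.delta_x, abs=t.delta_x_sd)

    def test_recovery_across_presets_within_one_sd(self, all_presets):
        """Round trip at reduced duration for the other three complexes."""
        from snarefold.hmm import analyze_separation_scan

        for name in ("glut4", "endosomal", "yeast"):
            p = all_presets[name]
            seps = p.ctd.suggested_separations(5)
            trajs = [
                simulate_constant_separation(p.ctd, d, 6.0, seed=900 + i)
                for i, d in enumerate(seps)
            ]
            scan = analyze_separation_scan(trajs)
            t = p.ctd.table
            assert scan.f_half == pytest.approx(t.f_half, abs=t.f_half_sd), name
            assert scan.delta_x_half == pytest.approx(t.delta_x, abs=t.delta_x_sd), name

    def test_exact_half_probability_returns_that_force(self):
        from snarefold.hmm import TwoStateHMMResults

        def res(p, f):
            return TwoStateHMMResults(
                state_means=np.array([0.0, 7.0]),
                state_sds=np.array([1.0, 1.0]),
                k_fold=100.0, k_unfold=100.0, p_unfold=p,
                f1=f + 0.35, f2=f - 0.35, n_transitions=500,
                idealized_path=np.zeros(2, dtype=int), log_likelihood=0.0,
                metadata={"separation": 900.0},
            )

        scan = equilibrium_force_scan([res(0.2, 15.0), res(0.5, 16.0), res(0.9, 17.0)])
        assert scan.f_half == 16.0

    def test_unbracketed_scan_rejected(self):
        from snarefold.hmm import TwoStateHMMResults

        rs = [
            TwoStateHMMResults(
                state_means=np.array([0.0, 7.0]), state_sds=np.array([1.0, 1.0]),
                k_fold=10.0, k_unfold=90.0, p_unfold=p, f1=f, f2=f,
                n_transitions=100, idealized_path=np.zeros(2, dtype=int),
                log_likelihood=0.0, metadata={},
            )
            for p, f in [(0.6, 15.0), (0.8, 16.0)]
        ]
        with pytest.raises(ValueError):
            equilibrium_force_scan(rs)
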