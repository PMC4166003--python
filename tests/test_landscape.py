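"""Energy-landscape predictions, fitting, work-based energies, spacer
correction and segment-average forces."""

import numpy as np
import pandas as pd
import pytest

from snarefold.landscape import (
    LandscapeModel,
    LandscapeParams,
    WorkMeasurement,
    average_segment_force,
    folding_energy_from_work,
    landscape_predictions,
    params_of_system,
    spacer_correction,
)
from snarefold.polymer import KBT_PN_NM, PolymerSegment, wlc_energy


class TestPredictions:
    def test_rate_ratio_equals_boltzmann_factor(self, all_presets):
        """k_unfold / k_fold == p / (1 - p) identically at every separation
        (exact algebraic identity of the model)."""
        for p in all_presets.values():
            for dom in ("ctd", "ld"):
                sys = getattr(p, dom)
                seps = sys.suggested_separations(9)
                pred = landscape_predictions(params_of_system(sys), sys, seps)
                ratio = pred["k_unfold"] / pred["k_fold"]
                odds = pred["p"] / (1 - pred["p"])
                assert np.allclose(ratio, odds, rtol=1e-9)

    def test_equal_system_energies_give_half_probability(self, neuronal):
        sys = neuronal.ctd
        pred = landscape_predictions(
            params_of_system(sys), sys, [sys.separation_half]
        ).iloc[0]
        assert pred["p"] == pytest.approx(0.5, abs=1e-9)
        assert pred["k_fold"] == pytest.approx(pred["k_unfold"], rel=1e-9)

    def test_neuronal_probability_crosses_half_at_published_force(self, neuronal):
        """p(F) crosses 0.5 at 16.2 pN for the neuronal CTD."""
        sys = neuronal.ctd
        seps = sys.suggested_separations(41)
        pred = landscape_predictions(params_of_system(sys), sys, seps)
        f_half = np.interp(0.5, pred["p"], pred["f_mean"])
        assert f_half == pytest.approx(16.2, abs=0.02)


class TestLandscapeFit:
    def test_noise_free_forward_data_recovered_exactly(self, neuronal):
        sys = neuronal.ctd
        truth = params_of_system(sys)
        data = landscape_predictions(truth, sys, sys.suggested_separations(7))
        data["n_transitions"] = 1000
        res = LandscapeModel(data, sys).fit()
        assert res.minimizer_result.chisqr < 1e-10
        assert res.g_fold == pytest.approx(truth.g_fold, abs=1e-3)
        assert res.l_ts_aa == pytest.approx(truth.l_ts_aa, abs=0.05)

    def test_recovery_from_noisy_forward_data(self, all_presets):
        """Forward-model round trip with binomial/Poisson noise: median
        recovery error over replicates within 2 kBT in the folding energy
        and 3 a.a. in the transition-state position."""
        rng = np.random.default_rng(2014)
        for name, preset in all_presets.items():
            sys = preset.ctd
            truth = params_of_system(sys)
            err_g, err_l = [], []
            n_rep = 6 if name == "neuronal" else 3
            for _ in range(n_rep):
                data = landscape_predictions(truth, sys, sys.suggested_separations(7))
                n = 600
                k_obs = rng.binomial(n, data["p"]) / n
                data["p"] = np.clip(k_obs, 1e-3, 1 - 1e-3)
                data["k_unfold"] = data["k_unfold"] * np.exp(rng.normal(0, 1 / np.sqrt(n), len(data)))
                data["k_fold"] = data["k_fold"] * np.exp(rng.normal(0, 1 / np.sqrt(n), len(data)))
                data["n_transitions"] = n
                res = LandscapeModel(data, sys).fit(starts=(0.5,))
                err_g.append(abs(res.g_fold - truth.g_fold))
                err_l.append(abs(res.l_ts_aa - truth.l_ts_aa))
            assert np.median(err_g) <= 2.0, name
            assert np.median(err_l) <= 3.0, name

    def test_fit_invariant_to_row_order(self, neuronal):
        sys = neuronal.ctd
        data = landscape_predictions(params_of_system(sys), sys, sys.suggested_separations(7))
        data["p"] = np.clip(data["p"] + 0.01, 0, 1)
        data["n_transitions"] = 500
        a = LandscapeModel(data, sys).fit(starts=(0.5,))
        b = LandscapeModel(data.iloc[::-1].reset_index(drop=True), sys).fit(starts=(0.5,))
        assert a.g_fold == pytest.approx(b.g_fold, abs=1e-6)

    def test_too_few_separations_rejected(self, neuronal):
        sys = neuronal.ctd
        data = landscape_predictions(params_of_system(sys), sys, sys.suggested_separations(2))
        with pytest.raises(ValueError):
            LandscapeModel(data, sys)

    def test_end_to_end_energy_recovery(self, neuronal_ctd_scan, neuronal):
        """Simulate -> HMM -> landscape fit recovers the published folding
        energy within its printed SD (4.7 kBT)."""
        res = LandscapeModel(neuronal_ctd_scan.table, neuronal.ctd).fit()
        t = neuronal.ctd.table
        assert res.g_fold == pytest.approx(t.delta_g, abs=t.delta_g_sd)
        assert res.l_ts_aa == pytest.approx(t.ts_position_aa, abs=3.0)


class TestWorkEnergy:
    def test_zero_peptide_stretch_reduces_to_work(self):
        m = WorkMeasurement(f_half=10.0, delta_x_total=5.0, delta_l=0.0, delta_x_peptide=0.0)
        assert folding_energy_from_work(m) == pytest.approx(10.0 * 5.0 / KBT_PN_NM)

    def test_neuronal_work_term_before_entropic_correction(self):
        """16.2 pN x 7.2 nm = 28.4 kBT."""
        m = WorkMeasurement(16.2, 7.2, 0.0, 0.0)
        assert folding_energy_from_work(m) == pytest.approx(28.45, abs=0.01)

    def test_consistent_with_landscape_fit_on_synthetic_scan(
        self, neuronal_ctd_scan, neuronal
    ):
        """The work-based estimate with the construct's effective contour
        agrees with the landscape fit within a few kBT (the DNA-handle and
        trap relaxation terms it neglects)."""
        sys = neuronal.ctd
        r_half = 0.6443  # peptide fractional extension at 16.2 pN
        m = WorkMeasurement(
            f_half=neuronal_ctd_scan.f_half,
            delta_x_total=neuronal_ctd_scan.delta_x_half,
            delta_l=sys.delta_contour,
            delta_x_peptide=r_half * sys.delta_contour,
        )
        res = LandscapeModel(neuronal_ctd_scan.table, sys).fit(starts=(0.5,))
        assert folding_energy_from_work(m) == pytest.approx(-res.g_fold, abs=5.0)


class TestSpacerCorrection:
    def test_identical_geometries_change_nothing(self):
        c = spacer_correction(-6.6, (23.7, 11.8), (23.7, 11.8))
        assert c.g_sp == 0.0
        assert c.g_corrected == -6.6

    def test_printed_arithmetic(self):
        """-6.6 - 3.1 = -9.7 kBT with the published spacer energy."""
        c = spacer_correction(-6.6, g_sp=3.1)
        assert c.g_corrected == pytest.approx(-9.7)

    def test_closed_form_spacer_energy(self):
        """Published spacer geometry (65 aa/23.7 nm at 11.8 nm folded vs
        73 aa/26.6 nm at 10.6 nm unfolded): the closed form gives 3.33 kBT
        (the printed rounded values yield 3.1)."""
        c = spacer_correction(-6.6, (23.7, 11.8), (26.6, 10.6))
        e_f = wlc_energy(PolymerSegment(23.7, 0.6), 11.8 / 23.7)
        e_u = wlc_energy(PolymerSegment(26.6, 0.6), 10.6 / 26.6)
        assert c.g_sp == pytest.approx(e_f - e_u, rel=1e-12)
        assert c.g_sp == pytest.approx(3.33, abs=0.01)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            spacer_correction(-6.6, (10.0, 12.0), (26.6, 10.6))


class TestAverageSegmentForce:
    def test_uniform_allocation_gives_equilibrium_force(self):
        e_total = 16.0 * 7.2 / KBT_PN_NM
        f = average_segment_force(e_total, 7.2, segment_fraction=0.4, energy_fraction=0.4)
        assert f == pytest.approx(16.0)

    def test_published_polarized_forces(self):
        """Two-thirds of the energy over the C-terminal third gives 32 pN;
        the remaining third over the N-terminal two-thirds gives 8 pN."""
        e_total = 16.0 * 7.2 / KBT_PN_NM
        assert average_segment_force(e_total, 7.2, 1 / 3, 2 / 3) == pytest.approx(32.0)
        assert average_segment_force(e_total, 7.2, 2 / 3, 1 / 3) == pytest.approx(8.0)

    def test_zero_length_segment_rejected(self):
        with pytest.raises(ValueError):
            average_segment_force(10.0, 7.2, 0.0, 0.5)


def test_landscape_params_invariants():
    with pytest.raises(ValueError):
        LandscapeParams(-27.0, -5.5, 17.0, 0.0)
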