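"""The synthetic-data generator: dwell statistics, detailed balance,
seed determinism, and pulling-cycle phenomenology."""

import numpy as np
import pandas as pd
import pytest

from snarefold.landscape import landscape_predictions, params_of_system
from snarefold.simulate import (
    observable_transitions,
    simulate_constant_separation,
    simulate_pull,
)


class TestConstantSeparation:
    def test_seed_determinism(self, neuronal):
        a = simulate_constant_separation(neuronal.ctd, neuronal.ctd.separation_half, 1.5, seed=5)
        b = simulate_constant_separation(neuronal.ctd, neuronal.ctd.separation_half, 1.5, seed=5)
        assert np.array_equal(a.extension, b.extension)
        assert np.array_equal(a.force, b.force)
        c = simulate_constant_separation(neuronal.ctd, neuronal.ctd.separation_half, 1.5, seed=6)
        assert not np.array_equal(a.extension, c.extension)

    def test_dwell_times_match_exponential_oracle(self, neuronal):
        """Mean dwell times in each state agree with 1/k within 3 SE over a
        10 s trace at ~100 1/s rates."""
        sys = neuronal.ctd
        traj = simulate_constant_separation(sys, sys.separation_half, 10.0, seed=11)
        states = traj.true_states
        switch = np.flatnonzero(np.diff(states) != 0)
        dt = traj.sampling_interval
        bounds = np.concatenate([[0], switch + 1, [len(states)]])
        durations = np.diff(bounds) * dt
        occupants = states[bounds[:-1]]
        for state, true_rate in ((0, traj.metadata["true_k_unfold"]), (1, traj.metadata["true_k_fold"])):
            dwells = durations[occupants == state][1:-1]  # drop censored ends
            se = dwells.mean() / np.sqrt(len(dwells))
            assert abs(dwells.mean() - 1.0 / true_rate) < 3 * se

    def test_extension_gap_matches_configured_delta_x(self, neuronal):
        sys = neuronal.ctd
        traj = simulate_constant_separation(sys, sys.separation_half, 8.0, seed=21)
        x, s = traj.extension, traj.true_states
        gap = x[s == 1].mean() - x[s == 0].mean()
        noise_se = 3.0 * np.sqrt(1 / (s == 1).sum() + 1 / (s == 0).sum())
        assert abs(gap - traj.metadata["true_gap"]) < 4 * noise_se

    def test_detailed_balance_occupancy(self, neuronal):
        """Long-run occupancy ratio matches the Boltzmann factor of the
        system-energy difference within 3 SE."""
        sys = neuronal.ctd
        d = sys.separation_half + 3.0  # tilted toward unfolding
        traj = simulate_constant_separation(sys, d, 10.0, seed=31)
        pred = landscape_predictions(params_of_system(sys), sys, [d]).iloc[0]
        s = traj.true_states
        p_hat = s.mean()
        n_eff = max(np.count_nonzero(np.diff(s)), 2)  # transitions, not samples
        se = np.sqrt(pred["p"] * (1 - pred["p"]) / n_eff)
        assert abs(p_hat - pred["p"]) < 3 * se

    def test_force_channel_is_trap_force(self, neuronal):
        sys = neuronal.ctd
        d = sys.separation_half
        traj = simulate_constant_separation(sys, d, 1.1, seed=41)
        k = sys.traps.effective_stiffness
        assert np.allclose(traj.force, k * (d - traj.extension))

    def test_duration_must_be_positive(self, neuronal):
        with pytest.raises(ValueError):
            simulate_constant_separation(neuronal.ctd, neuronal.ctd.separation_half, 0.0, seed=1)


class TestPulling:
    def test_frozen_pull_relax_overlap(self, neuronal):
        """With all transitions disabled, pulling and relaxing retrace the
        same single branch (reversible curve)."""
        d0 = neuronal.ctd.separation_half
        res = simulate_pull(
            neuronal, seed=3, cycles=1, d_range=(d0 - 10, d0 + 10),
            noise_sd=0.0, frozen=True, decimate=5,
        )
        assert set(res.fec["state"]) == {"folded"}
        assert len(res.events) == 0
        pull = res.fec[res.fec["phase"] == "pull"]
        relax = res.fec[res.fec["phase"] == "relax"]
        x_relax = np.interp(
            pull["trap_sep_nm"], relax["trap_sep_nm"][::-1], relax["extension_nm"][::-1]
        )
        assert np.allclose(x_relax, pull["extension_nm"], atol=1e-3)

    def test_seed_determinism(self, glut4):
        d0 = glut4.ctd.separation_half
        kw = dict(cycles=1, d_range=(d0 - 15, d0 + 15), decimate=10)
        a = simulate_pull(glut4, seed=9, **kw)
        b = simulate_pull(glut4, seed=9, **kw)
        pd.testing.assert_frame_equal(a.fec, b.fec)
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_many_ctd_transitions_before_ntd_unzip(self, glut4):
        """The GLUT4 complex shows of order 10-1e5 CTD transitions before
        NTD unzipping at the default 10 nm/s pull speed."""
        d0 = glut4.ctd.separation_half
        res = simulate_pull(glut4, seed=17, cycles=1, d_range=(d0 - 30, d0 + 50),
                            decimate=50, include_relax=False)
        ev = res.events
        unzips = ev[
            (ev["from_state"] == "half_zippered")
            & ev["to_state"].isin(["t_snare", "unfolded"])
        ]
        assert len(unzips) == 1
        t_unzip = unzips["time_s"].iloc[0]
        n_ctd = (
            (ev["time_s"] < t_unzip)
            & (ev["from_state"].isin(["ld_open", "half_zippered"]))
            & (ev["to_state"].isin(["ld_open", "half_zippered"]))
        ).sum()
        assert 10 <= n_ctd <= 1e5

    def test_ntd_unzip_force_distribution(self, neuronal):
        """Mean NTD unzip force across cycles within 3 SE of the preset
        mean (draws truncated at the CTD equilibrium force)."""
        from scipy.stats import truncnorm

        d0 = neuronal.ctd.separation_half
        res = simulate_pull(
            neuronal, seed=23, cycles=40, d_range=(d0 - 5, d0 + 45),
            decimate=200, include_relax=False,
        )
        ev = res.events
        is_unzip = (ev["from_state"] == "half_zippered") & ev["to_state"].isin(
            ["t_snare", "unfolded"]
        )
        f_unzip = ev.loc[is_unzip, "force_pN"]
        mu, sd = neuronal.ntd_unzip_force
        a = (neuronal.ctd.table.f_half - mu) / sd
        expected = truncnorm.mean(a, np.inf, loc=mu, scale=sd)
        se = sd / np.sqrt(len(f_unzip))
        assert len(f_unzip) >= 30
        assert abs(f_unzip.mean() - expected) < 3.5 * se

    def test_transient_intermediate_fraction(self, all_presets):
        """The fraction of unzipping events passing through the transient
        t-SNARE intermediate matches the preset probability (binomial CI
        over 200 pulls)."""
        preset = all_presets["glut4"]
        d0 = preset.ctd.separation_half
        res = simulate_pull(
            preset, seed=29, cycles=200, d_range=(d0 - 2, d0 + 40),
            decimate=500, include_relax=False,
        )
        ev = res.events
        unzip = ev[
            (ev["from_state"] == "half_zippered")
            & ev["to_state"].isin(["t_snare", "unfolded"])
        ]
        frac = (unzip["to_state"] == "t_snare").mean()
        n = len(unzip)
        p0 = preset.transient_probability
        se = np.sqrt(p0 * (1 - p0) / n)
        assert n >= 150
        assert abs(frac - p0) < 3 * se

    def test_reassembly_below_four_piconewtons(self, neuronal):
        """On relax the fully unfolded complex reassembles cooperatively
        once the force drops to ~4 pN."""
        d0 = neuronal.ctd.separation_half
        res = simulate_pull(
            neuronal, seed=37, cycles=1, d_range=(d0 - 130, d0 + 45), decimate=100,
        )
        re_ev = res.events[res.events["to_state"] == "folded"]
        re_ev = re_ev[re_ev["from_state"].isin(["unfolded", "t_snare"])]
        if len(re_ev):  # the cycle reached full unfolding
            assert (re_ev["force_pN"] <= neuronal.reassembly_force + 0.2).all()


def test_observable_transitions_collapses_fast_flickers():
    ev = pd.DataFrame(
        {
            "time_s": [0.0, 0.001, 0.5, 0.8],
            "cycle": 0,
            "phase": "pull",
            "trap_sep_nm": 900.0,
            "from_state": ["ld_open", "half_zippered", "ld_open", "half_zippered"],
            "to_state": ["half_zippered", "ld_open", "half_zippered", "unfolded"],
            "force_pN": 15.0,
            "jump_nm": [7.0, -7.0, 7.0, 12.0],
        }
    )
    obs = observable_transitions(ev, dead_time=5e-3)
    assert len(obs) == 2
    assert list(obs["time_s"]) == [0.5, 0.8]
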