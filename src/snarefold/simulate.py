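"""Synthetic single-molecule data with the statistical structure of the assay.

Two experiments are emulated:

* **Constant trap separation** — the molecule hops between the folded and
  unfolded branches of one two-state transition as a continuous-time Markov
  chain whose rates follow from the preset's energy landscape; the recorded
  extension is the state branch extension plus white Gaussian noise at the
  10 kHz sampling rate, and the force channel is the trap force
  ``k (D - extension)``.

* **Pulling cycles** — the trap separation ramps at constant speed (typically
  10 nm/s); the molecule moves quasi-statically along the current state
  branch with stochastic transitions: reversible LD and CTD transitions with
  separation-dependent rates (piecewise-constant thinning, rates refreshed
  every millisecond of simulated time), irreversible NTD unzipping at a force
  drawn per cycle, an optional transient t-SNARE intermediate, and
  cooperative reassembly once the relaxing force drops below ~4 pN.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import landscape_predictions, params_of_system
from .presets import Preset, TwoStateSystem
from .tether import TrapSystem, branch_lookup_tables, interp_branch

DEFAULT_SAMPLING_HZ = 1.0e4
DEFAULT_NOISE_SD_NM = 3.0  # per raw 0.1 ms sample, before any filtering


@dataclass
class Trajectory:
    """A constant-trap-separation extension/force time series."""

    time: np.ndarray  # s
    extension: np.ndarray  # nm
    force: np.ndarray  # pN
    metadata: dict = field(default_factory=dict)
    true_states: np.ndarray | None = None  # 0 = folded, 1 = unfolded

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.extension) == len(self.force)):
            raise ValueError("time, extension and force must have equal length")

    @property
    def sampling_interval(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "extension_nm": self.extension, "force_pN": self.force}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, **metadata) -> "Trajectory":
        df = pd.read_csv(path, sep="\t")
        return cls(
            time=df["time_s"].to_numpy(),
            extension=df["extension_nm"].to_numpy(),
            force=df["force_pN"].to_numpy(),
            metadata=metadata,
        )


def _sample_dwells(
    rng: np.random.Generator,
    k01: float,
    k10: float,
    duration: float,
    start_state: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact two-state CTMC path: (switch times, states between switches)."""
    times = [0.0]
    states = [start_state]
    t, s = 0.0, start_state
    rates = (k01, k10)
    while True:
        rate = rates[s]
        t += rng.exponential(1.0 / rate) if rate > 0 else math.inf
        if t >= duration:
            break
        s = 1 - s
        times.append(t)
        states.append(s)
    return np.asarray(times), np.asarray(states)


def simulate_constant_separation(
    system: TwoStateSystem,
    separation: float,
    duration: float,
    seed: int,
    noise_sd: float = DEFAULT_NOISE_SD_NM,
    sampling_hz: float = DEFAULT_SAMPLING_HZ,
) -> Trajectory:
    """Simulate two-state hopping of one domain at fixed trap separation."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    pred = landscape_predictions(
        params_of_system(system), system, [separation]
    ).iloc[0]
    k_unfold, k_fold = float(pred["k_unfold"]), float(pred["k_fold"])
    p = float(pred["p"])
    k = system.traps.effective_stiffness
    x_state = np.array(
        [separation - pred["f1"] / k, separation - pred["f2"] / k]
    )  # folded, unfolded tether extensions

    start = int(rng.random() < p)  # draw the initial state from equilibrium
    switch_t, switch_s = _sample_dwells(rng, k_unfold, k_fold, duration, start)

    n = int(round(duration * sampling_hz))
    t = np.arange(n) / sampling_hz
    idx = np.searchsorted(switch_t, t, side="right") - 1
    states = switch_s[idx]
    extension = x_state[states] + rng.normal(0.0, noise_sd, size=n)
    force = k * (separation - extension)
    return Trajectory(
        time=t,
        extension=extension,
        force=force,
        metadata={
            "preset": system.preset,
            "domain": system.domain,
            "seed": seed,
            "separation": separation,
            "stiffness": k,
            "sampling_hz": sampling_hz,
            "noise_sd": noise_sd,
            "true_k_unfold": k_unfold,
            "true_k_fold": k_fold,
            "true_p": p,
            "true_gap": float(x_state[1] - x_state[0]),
        },
        true_states=states,
    )


# ---------------------------------------------------------------------------
# Pulling cycles
# ---------------------------------------------------------------------------

_STATE_ORDER = ("folded", "ld_open", "half_zippered", "t_snare", "unfolded")


@dataclass
class PullResult:
    """Force-extension curves of one or more pulling cycles plus the ground
    truth event log."""

    fec: pd.DataFrame  # time_s, cycle, phase, trap_sep_nm, extension_nm, force_pN, state
    events: pd.DataFrame  # time_s, cycle, phase, trap_sep_nm, from_state, to_state, force_pN, jump_nm
    metadata: dict = field(default_factory=dict)

    def cycle(self, i: int) -> pd.DataFrame:
        return self.fec[self.fec["cycle"] == i]


def _rate_tables(preset: Preset, d_grid: np.ndarray) -> dict[str, np.ndarray]:
    """Separation-dependent LD and CTD transition rates on a grid."""
    out: dict[str, np.ndarray] = {"D": d_grid}
    for dom in ("ld", "ctd"):
        system: TwoStateSystem = getattr(preset, dom)
        pred = landscape_predictions(params_of_system(system), system, d_grid)
        out[f"{dom}_unfold"] = pred["k_unfold"].to_numpy()
        out[f"{dom}_fold"] = pred["k_fold"].to_numpy()
    return out


def simulate_pull(
    preset: Preset,
    seed: int,
    cycles: int = 1,
    traps: TrapSystem | None = None,
    d_range: tuple[float, float] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD_NM,
    sampling_hz: float = DEFAULT_SAMPLING_HZ,
    decimate: int = 1,
    frozen: bool = False,
    include_relax: bool = True,
    rate_block: float = 1e-3,
    start_state: str = "folded",
) -> PullResult:
    """Simulate pulling (and optionally relaxing) cycles of a preset complex.

    ``frozen=True`` disables all transitions (the molecule rides a single
    branch reversibly); ``decimate`` keeps every n-th sample of the emitted
    10 kHz record.  Rates are treated as piecewise constant over
    ``rate_block`` seconds of simulated time, which at 10 nm/s changes the
    trap separation by only 0.1 pm per block.
    """
    rng = np.random.default_rng(seed)
    traps = traps or preset.traps
    speed = traps.pull_speed
    if speed <= 0:
        raise ValueError("pull_speed must be > 0")
    if d_range is None:
        lo = preset.ld.separation_half - 40.0
        hi = preset.ctd.separation_half + 80.0
        d_range = (lo, hi)
    d_lo, d_hi = d_range
    if d_hi <= d_lo:
        raise ValueError("d_range must be increasing")

    states = {s.name: s for s in preset.construct.states}
    tables = branch_lookup_tables(
        preset.construct.states, preset.construct, traps, d_lo - 1.0, d_hi + 1.0, 1.0
    )
    rates = _rate_tables(preset, np.arange(d_lo - 1.0, d_hi + 2.0, 2.0))

    def branch_force(state: str, d: float) -> float:
        return float(np.interp(d, tables[state]["D"], tables[state]["force"]))

    def rate_at(name: str, d: float) -> float:
        return float(np.interp(d, rates["D"], rates[name]))

    fec_rows: list[pd.DataFrame] = []
    ev_rows: list[dict] = []

    dt_block = rate_block
    for cyc in range(cycles):
        state = start_state
        phases = [("pull", d_lo, d_hi)]
        if include_relax:
            phases.append(("relax", d_hi, d_lo))
        f_unzip = float(
            max(
                rng.normal(*preset.ntd_unzip_force),
                preset.ctd.table.f_half,
            )
        )
        go_transient = rng.random() < preset.transient_probability
        transient_life = rng.exponential(preset.transient_lifetime)
        t0_cycle = cyc * (d_hi - d_lo) / speed * len(phases)
        t_unzip_pending = None  # phase-local time the t-SNARE intermediate expires

        for phase, d_start, d_end in phases:
            sign = 1.0 if d_end > d_start else -1.0
            t_phase = abs(d_end - d_start) / speed
            # Walk the state machine in blocks; record switch times.
            sw_t = [0.0]
            sw_s = [state]
            t = 0.0
            if state == "t_snare" and t_unzip_pending is None:
                # memoryless residual lifetime when entering a new phase
                t_unzip_pending = rng.exponential(preset.transient_lifetime)
            while t < t_phase:
                d = d_start + sign * speed * t
                dt = min(dt_block, t_phase - t)
                if frozen:
                    t += dt
                    continue
                if state == "folded":
                    k_out = {"ld_open": rate_at("ld_unfold", d)}
                elif state == "ld_open":
                    k_out = {
                        "folded": rate_at("ld_fold", d),
                        "half_zippered": rate_at("ctd_unfold", d),
                    }
                elif state == "half_zippered":
                    k_out = {"ld_open": rate_at("ctd_fold", d)}
                    # NTD unzipping: threshold on the current branch force
                    if branch_force(state, d) >= f_unzip:
                        nxt = "t_snare" if go_transient else "unfolded"
                        state = nxt
                        if nxt == "t_snare":
                            t_unzip_pending = t + transient_life
                        sw_t.append(t)
                        sw_s.append(state)
                        ev_rows.append(
                            _event(cyc, phase, t0_cycle + t, d, "half_zippered", nxt, tables, traps)
                        )
                        continue
                elif state == "t_snare":
                    k_out = {}
                    if (
                        phase == "relax"
                        and branch_force(state, d) <= preset.reassembly_force
                    ):
                        state = "folded"
                        t_unzip_pending = None
                        sw_t.append(t)
                        sw_s.append(state)
                        ev_rows.append(
                            _event(cyc, phase, t0_cycle + t, d, "t_snare", "folded", tables, traps)
                        )
                        continue
                    if t_unzip_pending is not None and t >= t_unzip_pending:
                        state = "unfolded"
                        sw_t.append(t)
                        sw_s.append(state)
                        ev_rows.append(
                            _event(cyc, phase, t0_cycle + t, d, "t_snare", "unfolded", tables, traps)
                        )
                        t_unzip_pending = None
                        continue
                else:  # unfolded
                    k_out = {}
                    if phase == "relax" and branch_force(state, d) <= preset.reassembly_force:
                        state = "folded"
                        sw_t.append(t)
                        sw_s.append(state)
                        ev_rows.append(
                            _event(cyc, phase, t0_cycle + t, d, "unfolded", "folded", tables, traps)
                        )
                        continue
                total = sum(k_out.values())
                if total > 0:
                    wait = rng.exponential(1.0 / total)
                    if wait < dt:
                        u = rng.random() * total
                        acc = 0.0
                        for nxt, rate in k_out.items():
                            acc += rate
                            if u <= acc:
                                break
                        t += wait
                        d = d_start + sign * speed * t
                        ev_rows.append(
                            _event(cyc, phase, t0_cycle + t, d, state, nxt, tables, traps)
                        )
                        state = nxt
                        sw_t.append(t)
                        sw_s.append(state)
                        continue
                t += dt

            # Emit samples for this phase.
            n = int(round(t_phase * sampling_hz))
            ts = np.arange(n) / sampling_hz
            ds = d_start + sign * speed * ts
            idx = np.searchsorted(np.asarray(sw_t), ts, side="right") - 1
            state_names = np.asarray(sw_s, dtype=object)[idx]
            x = np.empty(n)
            for name in np.unique(state_names):
                m = state_names == name
                x[m] = np.interp(ds[m], tables[name]["D"], tables[name]["extension"])
            x += rng.normal(0.0, noise_sd, size=n)
            f = traps.effective_stiffness * (ds - x)
            if t_unzip_pending is not None:
                t_unzip_pending = max(t_unzip_pending - t_phase, 0.0)
            df = pd.DataFrame(
                {
                    "time_s": t0_cycle + ts,
                    "cycle": cyc,
                    "phase": phase,
                    "trap_sep_nm": ds,
                    "extension_nm": x,
                    "force_pN": f,
                    "state": state_names,
                }
            )
            if decimate > 1:
                df = df.iloc[::decimate]
            fec_rows.append(df)
            t0_cycle += t_phase

    fec = pd.concat(fec_rows, ignore_index=True)
    events = pd.DataFrame(
        ev_rows,
        columns=[
            "time_s",
            "cycle",
            "phase",
            "trap_sep_nm",
            "from_state",
            "to_state",
            "force_pN",
            "jump_nm",
        ],
    )
    return PullResult(
        fec=fec,
        events=events,
        metadata={
            "preset": preset.name,
            "seed": seed,
            "cycles": cycles,
            "speed": speed,
            "d_range": d_range,
            "noise_sd": noise_sd,
            "sampling_hz": sampling_hz,
            "decimate": decimate,
        },
    )


def _event(cyc, phase, t_abs, d, from_state, to_state, tables, traps) -> dict:
    f_before, x_before = interp_branch(tables[from_state], d)
    f_after, x_after = interp_branch(tables[to_state], d)
    return {
        "time_s": float(t_abs),
        "cycle": cyc,
        "phase": phase,
        "trap_sep_nm": float(d),
        "from_state": from_state,
        "to_state": to_state,
        "force_pN": float(f_before),
        "jump_nm": float(x_after - x_before),
    }


def observable_transitions(
    events: pd.DataFrame, dead_time: float, min_jump: float = 0.0
) -> pd.DataFrame:
    """Collapse ground-truth transitions a finite-bandwidth detector cannot
    resolve: successive events separated by less than ``dead_time`` within a
    cycle/phase annihilate pairwise (the intervening dwell is unobservable),
    and events with |jump| <= ``min_jump`` are dropped."""
    keep: list[pd.Series] = []
    for (_, _), grp in events.groupby(["cycle", "phase"], sort=True):
        rows = [r for _, r in grp.sort_values("time_s").iterrows()]
        changed = True
        while changed and len(rows) >= 2:
            changed = False
            for i in range(len(rows) - 1):
                if (
                    rows[i + 1]["time_s"] - rows[i]["time_s"] < dead_time
                    and rows[i + 1]["from_state"] == rows[i]["to_state"]
                    and rows[i + 1]["to_state"] == rows[i]["from_state"]
                ):
                    del rows[i : i + 2]
                    changed = True
                    break
        keep.extend(rows)
    out = pd.DataFrame(keep).reset_index(drop=True) if keep else events.iloc[:0]
    if min_jump > 0 and len(out):
        out = out[np.abs(out["jump_nm"]) > min_jump].reset_index(drop=True)
    return out
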