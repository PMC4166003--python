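"""Segmentation and state assignment of force-extension curves.

A pulling-cycle record is segmented into continuous branches at the abrupt
extension changes ("rips") produced by cooperative protein transitions; each
branch is fitted with the tether model (DNA handle + unfolded polypeptide +
structured extension) with the unfolded contour length as the free
parameter, and labelled with the nearest construct state.  First-unzip
statistics compare the first CTD and first NTD unzipping events of each
pulling cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .polymer import NM_PER_AA, PolymerSegment, wlc_extension
from .tether import ConstructModel, TrapSystem

__all__ = [
    "RipEvent",
    "detect_rips",
    "BranchAssignment",
    "assign_states",
    "UnzipStats",
    "first_unzip_stats",
]

#: Raw sampling assumed when a record carries no explicit rate.
_DEFAULT_DT = 1e-4


@dataclass(frozen=True)
class RipEvent:
    """An abrupt extension change at near-constant trap separation."""

    time: float  # s
    force: float  # pN, immediately before the jump
    jump: float  # nm, signed extension change
    direction: str  # "unfold" (extension increase) or "refold"
    cycle: int
    phase: str
    index: int  # sample index of the jump centre
    from_state: str | None = None
    to_state: str | None = None


def _sampling_interval(fec: pd.DataFrame) -> float:
    t = fec["time_s"].to_numpy()
    return float(np.median(np.diff(t[: min(len(t), 1000)]))) if len(t) > 1 else _DEFAULT_DT


def detect_rips(
    fec: pd.DataFrame,
    threshold: float = 3.0,
    filter_window: float = 5e-3,
) -> list[RipEvent]:
    """Detect rips in a phase-labelled FEC record.

    The extension is mean-filtered (default 5 ms); a rip is a local extremum
    of the filtered two-sided difference over the filter window exceeding
    ``threshold`` nm.  Deterministic given the record.
    """
    if "phase" not in fec.columns:
        raise ValueError("FEC record must carry a 'phase' column (pull/relax)")
    from .hmm import mean_filter

    events: list[RipEvent] = []
    key_cols = ["cycle", "phase"] if "cycle" in fec.columns else ["phase"]
    for key, grp in fec.groupby(key_cols, sort=False):
        if len(key_cols) == 2:
            cycle, phase = key
        else:
            cycle, (phase,) = 0, key
        dt = _sampling_interval(grp)
        w = max(int(filter_window / dt), 1)
        x = mean_filter(grp["extension_nm"].to_numpy(), filter_window, dt)
        if len(x) < 2 * w + 1:
            continue
        d = x[2 * w :] - x[: -2 * w]  # two-sided difference across the window
        exceed = np.abs(d) > threshold
        if not exceed.any():
            continue
        # group contiguous exceedances, keep the extremum of each
        idx = np.flatnonzero(exceed)
        splits = np.flatnonzero(np.diff(idx) > w) + 1
        t = grp["time_s"].to_numpy()
        f = grp["force_pN"].to_numpy()
        for run in np.split(idx, splits):
            j = run[np.argmax(np.abs(d[run]))]
            centre = j + w
            jump = float(d[j])
            pre = slice(max(centre - 2 * w, 0), max(centre - w, 1))
            events.append(
                RipEvent(
                    time=float(t[centre]),
                    force=float(np.mean(f[pre])),
                    jump=jump,
                    direction="unfold" if jump > 0 else "refold",
                    cycle=int(cycle),
                    phase=str(phase),
                    index=int(grp.index[centre]),
                )
            )
    events.sort(key=lambda e: e.time)
    return events


@dataclass(frozen=True)
class BranchAssignment:
    """A continuous FEC branch fitted with the tether model."""

    start_time: float
    end_time: float
    n_points: int
    contour_estimate: float  # nm, unfolded contour of the best fit
    residual_rms: float  # nm
    state: str | None  # nearest construct state, None if unassigned
    state_distance_aa: float  # |contour - state contour| in amino acids


def _h_of_contour(construct: ConstructModel) -> tuple[np.ndarray, np.ndarray]:
    ls = np.array([s.unfolded_contour for s in construct.states])
    hs = np.array([s.structured_extension for s in construct.states])
    order = np.argsort(ls)
    return ls[order], hs[order]


def assign_states(
    fec: pd.DataFrame,
    construct: ConstructModel,
    traps: TrapSystem | None = None,
    threshold: float = 3.0,
    filter_window: float = 5e-3,
    min_points: int = 20,
    max_state_distance_aa: float = 5.0,
    events: list[RipEvent] | None = None,
) -> list[BranchAssignment]:
    """Fit each continuous branch between rips with the tether model.

    The unfolded contour length is the free parameter; the structured
    extension is interpolated between construct states on the contour
    coordinate.  Branches shorter than ``min_points`` are merged forward.
    A branch is labelled with the nearest construct state unless it is more
    than ``max_state_distance_aa`` amino acids away.
    """
    if events is None:
        events = detect_rips(fec, threshold=threshold, filter_window=filter_window)
    cut_indices = sorted(e.index for e in events)
    ls_grid, hs_grid = _h_of_contour(construct)
    sorted_names = [
        s.name for s in sorted(construct.states, key=lambda s: s.unfolded_contour)
    ]
    l_max = ls_grid[-1] + 40.0

    # branch boundaries: phase boundaries plus rips
    boundaries = [fec.index[0]]
    key = ["cycle", "phase"] if "cycle" in fec.columns else ["phase"]
    for _, grp in fec.groupby(key, sort=False):
        boundaries.append(grp.index[0])
    boundaries += cut_indices + [fec.index[-1] + 1]
    boundaries = sorted(set(boundaries))

    segments = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        seg = fec.loc[a : b - 1]
        if len(seg) == 0:
            continue
        if segments and len(seg) < min_points:
            segments[-1] = pd.concat([segments[-1], seg])
        else:
            segments.append(seg)

    out: list[BranchAssignment] = []
    for seg in segments:
        if len(seg) < min_points:
            continue
        # subsample long branches: the fit is over-determined anyway
        step = max(len(seg) // 400, 1)
        f = seg["force_pN"].to_numpy()[::step]
        x = seg["extension_nm"].to_numpy()[::step]
        ok = f > 0.5  # the WLC fit is uninformative at vanishing force
        if ok.sum() < min_points // 2:
            continue
        f, x = f[ok], x[ok]
        x_dna = wlc_extension(construct.dna_handle, f)

        def rms(l: float) -> float:
            h = np.interp(l, ls_grid, hs_grid)
            pep = PolymerSegment(l, construct.peptide_persistence)
            model = h + wlc_extension(pep, f) + x_dna
            return float(np.sqrt(np.mean((x - model) ** 2)))

        res = minimize_scalar(rms, bounds=(0.0, l_max), method="bounded")
        l_hat = float(res.x)
        dist = np.abs(ls_grid - l_hat) / NM_PER_AA
        i = int(np.argmin(dist))
        state = sorted_names[i] if dist[i] <= max_state_distance_aa else None
        out.append(
            BranchAssignment(
                start_time=float(seg["time_s"].iloc[0]),
                end_time=float(seg["time_s"].iloc[-1]),
                n_points=len(seg),
                contour_estimate=l_hat,
                residual_rms=float(res.fun),
                state=state,
                state_distance_aa=float(dist[i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# First-unzip statistics
# ---------------------------------------------------------------------------

_CTD_UNFOLD = {("ld_open", "half_zippered")}
_NTD_UNZIP = {("half_zippered", "t_snare"), ("half_zippered", "unfolded")}


@dataclass
class UnzipStats:
    """Aggregated first-unzip statistics over pulling cycles."""

    f_unzip_mean: float  # pN, mean NTD unzipping force
    f_unzip_sd: float
    delta_f_mean: float  # pN, first NTD minus first CTD unzip force
    delta_f_sd: float
    delta_t_mean: float  # s
    delta_t_sd: float
    n_transitions: int  # N_T, NTD unzip events scored
    n_cycles: int  # cycles contributing both events
    n_skipped: int
    per_cycle: pd.DataFrame = field(repr=False, default=None)


def first_unzip_stats(events: pd.DataFrame) -> UnzipStats:
    """Per-cycle force/time differences of the first NTD and CTD unzipping
    events, from a labelled event table (columns ``cycle``, ``phase``,
    ``time_s``, ``force_pN``, ``from_state``, ``to_state``).

    Cycles missing either event are skipped (counted in ``n_skipped``).
    """
    rows = []
    n_skipped = 0
    pulls = events[events["phase"] == "pull"] if "phase" in events.columns else events
    for cyc, grp in pulls.groupby("cycle", sort=True):
        pairs = list(zip(grp["from_state"], grp["to_state"]))
        is_ctd = np.array([p in _CTD_UNFOLD for p in pairs])
        is_ntd = np.array([p in _NTD_UNZIP for p in pairs])
        if not is_ctd.any() or not is_ntd.any():
            n_skipped += 1
            continue
        first_ctd = grp[is_ctd].sort_values("time_s").iloc[0]
        first_ntd = grp[is_ntd].sort_values("time_s").iloc[0]
        rows.append(
            {
                "cycle": cyc,
                "f_ctd": float(first_ctd["force_pN"]),
                "f_unzip": float(first_ntd["force_pN"]),
                "delta_f": float(first_ntd["force_pN"] - first_ctd["force_pN"]),
                "delta_t": float(first_ntd["time_s"] - first_ctd["time_s"]),
            }
        )
    per_cycle = pd.DataFrame(rows)
    if len(per_cycle) == 0:
        return UnzipStats(
            math.nan, math.nan, math.nan, math.nan, math.nan, math.nan,
            0, 0, n_skipped, per_cycle,
        )
    return UnzipStats(
        f_unzip_mean=float(per_cycle["f_unzip"].mean()),
        f_unzip_sd=float(per_cycle["f_unzip"].std(ddof=1)) if len(per_cycle) > 1 else 0.0,
        delta_f_mean=float(per_cycle["delta_f"].mean()),
        delta_f_sd=float(per_cycle["delta_f"].std(ddof=1)) if len(per_cycle) > 1 else 0.0,
        delta_t_mean=float(per_cycle["delta_t"].mean()),
        delta_t_sd=float(per_cycle["delta_t"].std(ddof=1)) if len(per_cycle) > 1 else 0.0,
        n_transitions=len(per_cycle),
        n_cycles=len(per_cycle),
        n_skipped=n_skipped,
        per_cycle=per_cycle,
    )
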