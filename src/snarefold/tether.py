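"""Series mechanics of the dumbbell assay: beads, DNA handle, protein.

A single SNARE complex is held between two optically trapped beads through a
double-stranded DNA handle.  At a given assembly state the tether extension is
the sum of a force-independent structured extension ``h``, the WLC extension
of the unfolded polypeptide and the WLC extension of the handle; the two traps
act as one effective harmonic spring of stiffness ``k`` in series with the
tether.  At fixed trap separation ``D`` the force ``F`` balances

    D = h + x_peptide(F) + x_handle(F) + F / k,

and the total system energy of a state is its folding free energy plus the
entropic energies of the stretched chains plus the trap energy F^2 / (2 k).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .polymer import (
    KBT_PN_NM,
    NM_PER_BP,
    PolymerSegment,
    wlc_energy,
    wlc_extension,
)

#: Default DNA handle: 2260 bp of B-DNA at 0.34 nm/bp, P = 40 nm.
DEFAULT_HANDLE = PolymerSegment(2260 * NM_PER_BP, 40.0)

#: Persistence length of unfolded polypeptide, nm.
PEPTIDE_PERSISTENCE_NM = 0.6

_F_MAX = 400.0  # pN, upper bracket for force-balance root finding


class InfeasibleSeparationError(ValueError):
    """Raised when no force in [0, F_max] balances the requested separation."""


@dataclass(frozen=True)
class FoldingState:
    """One assembly state of the SNARE construct.

    ``zipper_position`` is the last zippered amino acid of the R SNARE,
    counted from the ionic layer (layer 0; negative = NTD side).
    ``unfolded_contour`` is the total contour length (nm) of unstructured
    polypeptide in the pulling path; ``structured_extension`` the
    force-independent extension ``h`` (nm) of the folded portion;
    ``folding_energy`` the state free energy in kBT relative to the
    reference (most unfolded) state of its transition.
    """

    name: str
    unfolded_contour: float
    structured_extension: float
    folding_energy: float = 0.0
    zipper_position: float | None = None

    def __post_init__(self) -> None:
        if self.unfolded_contour < 0:
            raise ValueError("unfolded_contour must be >= 0")
        if self.structured_extension < 0:
            raise ValueError("structured_extension must be >= 0")


@dataclass(frozen=True)
class ConstructModel:
    """The protein-DNA conjugate: ordered assembly states plus the handle."""

    states: tuple[FoldingState, ...]
    dna_handle: PolymerSegment = DEFAULT_HANDLE
    peptide_persistence: float = PEPTIDE_PERSISTENCE_NM
    #: (contour nm, endpoint distance nm) pairs for chimera spacer sequences;
    #: used only by the spacer free-energy bookkeeping, not the mechanics.
    spacers: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError("a construct needs at least two states")
        contours = [s.unfolded_contour for s in self.states]
        if any(b < a for a, b in zip(contours, contours[1:])):
            raise ValueError("states must be ordered by unfolded contour length")

    def peptide(self, state: FoldingState) -> PolymerSegment:
        return PolymerSegment(state.unfolded_contour, self.peptide_persistence)

    def state_by_name(self, name: str) -> FoldingState:
        for s in self.states:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class TrapSystem:
    """The two traps collapsed into one effective harmonic spring."""

    effective_stiffness: float = 0.1  # pN/nm
    pull_speed: float = 10.0  # nm/s

    def __post_init__(self) -> None:
        if self.effective_stiffness <= 0:
            raise ValueError("effective_stiffness must be > 0")
        if self.pull_speed < 0:
            raise ValueError("pull_speed must be >= 0")


def state_extension(
    state: FoldingState, construct: ConstructModel, force: float
) -> float:
    """Tether extension (nm) of ``state`` at ``force`` (pN): structured part
    plus unfolded-peptide and DNA-handle WLC extensions."""
    if force < 0:
        raise ValueError("force must be >= 0")
    return (
        state.structured_extension
        + wlc_extension(construct.peptide(state), force)
        + wlc_extension(construct.dna_handle, force)
    )


def _segment_compliance(seg: PolymerSegment, force: float, kbt: float) -> float:
    """dx/dF (nm/pN) of a WLC segment at the given force."""
    if seg.contour_length == 0:
        return 0.0
    from .polymer import inverse_wlc_ratio

    r = inverse_wlc_ratio(seg.persistence_length, force, kbt)
    dphi_dr = 0.5 / (1.0 - r) ** 3 + 1.0
    return seg.contour_length * seg.persistence_length / (kbt * dphi_dr)


def balance_force(
    state: FoldingState,
    construct: ConstructModel,
    traps: TrapSystem,
    separation: float,
    kbt: float = KBT_PN_NM,
) -> float:
    """Force balancing trap separation ``D``: root of
    ``D - extension(F) - F/k`` (residual < 1e-6 nm).

    Newton iteration with the analytic series compliance; falls back to
    bracketed root finding if it fails to converge.
    """
    k = traps.effective_stiffness

    def residual(f: float) -> float:
        return separation - state_extension(state, construct, f) - f / k

    if residual(0.0) < 0:
        raise InfeasibleSeparationError(
            f"separation {separation:.2f} nm shorter than slack tether"
        )
    if residual(_F_MAX) > 0:
        raise InfeasibleSeparationError(
            f"separation {separation:.2f} nm not reachable below {_F_MAX} pN"
        )
    f = k * max(separation - state.structured_extension, 0.0) * 0.5
    f = min(f, _F_MAX)
    for _ in range(100):
        res = residual(f)
        slope = (
            _segment_compliance(construct.peptide(state), f, kbt)
            + _segment_compliance(construct.dna_handle, f, kbt)
            + 1.0 / k
        )
        step = res / slope
        f_new = min(max(f + step, 0.0), _F_MAX)
        if abs(f_new - f) < 1e-12:
            return f_new
        f = f_new
    if abs(residual(f)) < 1e-6:
        return f
    return brentq(residual, 0.0, _F_MAX, xtol=1e-9)


def balance_forces_vector(
    state: FoldingState,
    construct: ConstructModel,
    traps: TrapSystem,
    separations: np.ndarray,
    kbt: float = KBT_PN_NM,
) -> np.ndarray:
    """Vectorised Newton solve of the force balance over many separations.

    Assumes all separations are feasible (force in (0, F_max)); used by the
    landscape predictions where the scan is known to be well-posed.
    """
    from .polymer import inverse_wlc_ratio

    d = np.asarray(separations, dtype=float)
    k = traps.effective_stiffness
    pep, dna = construct.peptide(state), construct.dna_handle
    f = np.clip(k * (d - state.structured_extension) * 0.5, 1e-6, _F_MAX)
    for _ in range(100):
        r_p = (
            inverse_wlc_ratio(pep.persistence_length, f, kbt)
            if pep.contour_length > 0
            else 0.0
        )
        r_d = inverse_wlc_ratio(dna.persistence_length, f, kbt)
        x = (
            state.structured_extension
            + np.asarray(r_p) * pep.contour_length
            + r_d * dna.contour_length
        )
        res = d - x - f / k
        slope = 1.0 / k
        if pep.contour_length > 0:
            slope = slope + pep.contour_length * pep.persistence_length / (
                kbt * (0.5 / (1.0 - np.asarray(r_p)) ** 3 + 1.0)
            )
        slope = slope + dna.contour_length * dna.persistence_length / (
            kbt * (0.5 / (1.0 - r_d) ** 3 + 1.0)
        )
        step = res / slope
        f = np.clip(f + step, 0.0, _F_MAX)
        if np.all(np.abs(step) < 1e-12):
            break
    return f


def system_energy_vector(
    state: FoldingState,
    construct: ConstructModel,
    traps: TrapSystem,
    separations: np.ndarray,
    kbt: float = KBT_PN_NM,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised system energies and balancing forces over separations."""
    from .polymer import inverse_wlc_ratio, wlc_energy

    f = balance_forces_vector(state, construct, traps, separations, kbt)
    pep, dna = construct.peptide(state), construct.dna_handle
    e = np.full_like(f, state.folding_energy)
    if pep.contour_length > 0:
        e = e + wlc_energy(pep, inverse_wlc_ratio(pep.persistence_length, f, kbt), kbt)
    e = e + wlc_energy(dna, inverse_wlc_ratio(dna.persistence_length, f, kbt), kbt)
    e = e + f * f / (2.0 * traps.effective_stiffness) / kbt
    return e, f


def system_energy(
    state: FoldingState,
    construct: ConstructModel,
    traps: TrapSystem,
    separation: float,
    kbt: float = KBT_PN_NM,
) -> tuple[float, float]:
    """Total system free energy (kBT) of ``state`` at trap separation ``D``.

    Returns ``(energy, force)`` where the energy is the folding free energy
    plus the WLC entropic energies of peptide and handle plus the harmonic
    trap energy ``F^2 / (2 k)``, all at the balancing force.
    """
    f = balance_force(state, construct, traps, separation)
    pep = construct.peptide(state)
    handle = construct.dna_handle
    e = state.folding_energy
    if pep.contour_length > 0:
        e += wlc_energy(pep, wlc_extension(pep, f) / pep.contour_length, kbt)
    e += wlc_energy(handle, wlc_extension(handle, f) / handle.contour_length, kbt)
    e += f * f / (2.0 * traps.effective_stiffness) / kbt
    return e, f


def predict_fec_branch(
    state: FoldingState,
    construct: ConstructModel,
    traps: TrapSystem,
    separations: Sequence[float],
) -> pd.DataFrame:
    """Quasi-static force-extension branch of one state over a range of trap
    separations.  Infeasible separations are dropped (truncated branch)."""
    rows = []
    truncated = 0
    for d in np.asarray(separations, dtype=float):
        try:
            f = balance_force(state, construct, traps, d)
        except InfeasibleSeparationError:
            truncated += 1
            continue
        rows.append((d, state_extension(state, construct, f), f))
    out = pd.DataFrame(rows, columns=["trap_sep_nm", "extension_nm", "force_pN"])
    out["state"] = state.name
    out.attrs["truncated_points"] = truncated
    if truncated:
        import warnings

        warnings.warn(
            f"branch for state {state.name!r} truncated at {truncated} separations",
            stacklevel=2,
        )
    return out


def branch_lookup_tables(
    states: Sequence[FoldingState],
    construct: ConstructModel,
    traps: TrapSystem,
    d_min: float,
    d_max: float,
    step: float = 1.0,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-state interpolation tables D -> (force, extension) used by the
    simulators to avoid a root solve per sample."""
    grid = np.arange(d_min, d_max + step, step)
    tables: dict[str, dict[str, np.ndarray]] = {}
    for s in states:
        f = np.array([balance_force(s, construct, traps, d) for d in grid])
        x = grid - f / traps.effective_stiffness
        tables[s.name] = {"D": grid, "force": f, "extension": x}
    return tables


def interp_branch(table: dict[str, np.ndarray], d) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate (force, extension) of one state at trap separation(s)."""
    return (
        np.interp(d, table["D"], table["force"]),
        np.interp(d, table["D"], table["extension"]),
    )
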