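"""Parameter presets for the four representative SNARE complexes.

The neuronal (syntaxin 1A / SNAP-25B / VAMP2), GLUT4 (syntaxin 4 / SNAP-23 /
VAMP2), endosomal (syntaxin 13 / Vti1a / syntaxin 6 / VAMP4) and yeast
(Sso1 / Sec9 / Snc2) complexes differ mainly in the energetics of their
C-terminal-domain (CTD) and linker-domain (LD) zippering.  Each two-state
transition is summarised by its equilibrium force f1/2 (the mean of the
folded- and unfolded-state forces at unfolding probability 0.5), the
extension change between the two states at fixed trap separation, the folding
free energy at zero force, and the transition-state energy and position on
the 0.365 nm-per-residue contour coordinate.

A preset turns those measured summaries into a concrete mechanical two-state
system: the effective unfolded-contour change and structured-extension change
are solved numerically so that, in the series tether model (DNA handle +
unfolded peptide + effective trap spring), the system reproduces the quoted
equilibrium force, extension change and folding energy exactly at the
equilibrium trap separation.  The Kramers attempt rate is set from the
observed equilibrium transition rate (~100 1/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .polymer import KBT_PN_NM, PolymerSegment, wlc_extension
from .tether import (
    DEFAULT_HANDLE,
    ConstructModel,
    FoldingState,
    TrapSystem,
    state_extension,
    system_energy,
)

PRESET_NAMES = ("neuronal", "glut4", "endosomal", "yeast")


@dataclass(frozen=True)
class DomainTable:
    """Published two-state summary of one zippering domain (CTD or LD)."""

    f_half: float  # pN, equilibrium force at p = 0.5
    f_half_sd: float  # pN, quoted SD
    delta_x: float  # nm, extension change at p = 0.5 (constant trap separation)
    delta_x_sd: float
    delta_g: float  # kBT, folding energy (negative = stable fold)
    delta_g_sd: float
    g_ts: float  # kBT, transition-state energy relative to the unfolded state
    ts_position_aa: float  # a.a. C-terminal to the ionic layer
    zipper_folded: float  # a.a., zipper position of the folded state
    zipper_unfolded: float  # a.a., zipper position of the unfolded state
    rate_eq: float = 100.0  # 1/s, transition rate at the equilibrium force

    @property
    def ts_fraction_from_folded(self) -> float:
        """Transition-state position as a fraction of the folded->unfolded
        contour change."""
        return (self.zipper_folded - self.ts_position_aa) / (
            self.zipper_folded - self.zipper_unfolded
        )


# Two-state transition summaries for the four complexes.  CTD rows span the
# half-zippered state (R SNARE unzipped to -1/+3/+1/+3 a.a. from the ionic
# layer) to the CTD-folded state (+25); LD rows span +25 to +36 (SNARE motif
# plus linker).  Equilibrium transition rates are >50 1/s for all complexes
# (~100 1/s for the neuronal CTD); LD transitions are faster.
PUBLISHED_PARAMS: dict[str, dict[str, DomainTable]] = {
    "neuronal": {
        "ctd": DomainTable(16.2, 0.9, 7.2, 1.2, -27.0, 4.7, -5.5, 17.0, 25.0, -1.0, 100.0),
        "ld": DomainTable(8.0, 1.0, 4.7, 0.5, -9.7, 1.6, 5.5, 31.0, 36.0, 25.0, 200.0),
    },
    "glut4": {
        "ctd": DomainTable(18.5, 1.8, 6.0, 0.9, -23.0, 4.1, -0.8, 11.0, 25.0, 3.0, 100.0),
        "ld": DomainTable(8.6, 0.9, 5.6, 1.1, -12.0, 2.7, 2.0, 30.0, 36.0, 25.0, 200.0),
    },
    "endosomal": {
        "ctd": DomainTable(11.9, 0.9, 6.9, 0.4, -16.0, 1.5, 2.1, 12.0, 25.0, 1.0, 100.0),
        "ld": DomainTable(6.3, 1.2, 5.1, 1.8, -6.1, 2.4, 4.9, 32.0, 36.0, 25.0, 200.0),
    },
    "yeast": {
        "ctd": DomainTable(10.1, 1.4, 5.8, 0.8, -13.0, 2.5, 3.2, 13.0, 25.0, 3.0, 100.0),
        "ld": DomainTable(6.0, 1.6, 5.1, 1.2, -5.7, 2.0, 3.6, 32.0, 36.0, 25.0, 200.0),
    },
}

#: Fraction of half-zippered unfolding events passing through a transient
#: t-SNARE intermediate, and its mean lifetime (s).
TRANSIENT_INTERMEDIATE = {
    "neuronal": (0.10, 0.020),
    "glut4": (0.50, 0.020),
    "endosomal": (0.30, 0.020),
    "yeast": (0.85, 8.0),
}

#: NTD unzipping force distribution (mean, SD) in pN.  The distributions are
#: unimodal and sit above the CTD equilibrium force; exact parameters are
#: calibration choices (draws are truncated at the CTD equilibrium force).
NTD_UNZIP_FORCE = {
    "neuronal": (18.5, 1.5),
    "glut4": (19.5, 1.5),
    "endosomal": (14.0, 1.5),
    "yeast": (13.0, 1.5),
}

#: Force (pN) below which the fully unfolded complex reassembles on relax.
REASSEMBLY_FORCE_PN = 4.0

#: Baseline unstructured contour (nm) in the fully folded state (terminal
#: tails at the pulling sites) and structured extension of the folded bundle.
BASELINE_CONTOUR_NM = 3.65
H_FOLDED_NM = 2.0

#: Contour (nm) released by NTD unzipping plus t-SNARE disordering
#: (half-zippered -> fully unfolded), used for FEC branch placement.
NTD_CONTOUR_NM = 26.0


@dataclass(frozen=True)
class TwoStateSystem:
    """A fully specified mechanical two-state transition of one domain.

    ``folded``/``unfolded`` are the two tether states; ``ts`` carries the
    transition-state geometry and bare energy (all bare energies are relative
    to the unfolded state of this transition).  ``separation_half`` is the
    trap separation at which the two system energies balance.
    """

    preset: str
    domain: str
    table: DomainTable
    folded: FoldingState
    unfolded: FoldingState
    ts: FoldingState
    construct: ConstructModel
    traps: TrapSystem
    k_m: float  # 1/s, Kramers attempt rate
    separation_half: float  # nm

    @property
    def delta_contour(self) -> float:
        return self.unfolded.unfolded_contour - self.folded.unfolded_contour

    @property
    def zipper_span_aa(self) -> float:
        return self.table.zipper_folded - self.table.zipper_unfolded

    def ts_state(self, g_ts: float, fraction_from_folded: float) -> FoldingState:
        """Transition-state geometry at a given contour fraction, energies
        interpolated linearly between the two end states."""
        fr = fraction_from_folded
        return FoldingState(
            name="ts",
            unfolded_contour=self.folded.unfolded_contour + fr * self.delta_contour,
            structured_extension=self.folded.structured_extension
            + fr
            * (self.unfolded.structured_extension - self.folded.structured_extension),
            folding_energy=g_ts,
        )

    def suggested_separations(
        self, n: int = 7, p_range: tuple[float, float] = (0.1, 0.9)
    ) -> np.ndarray:
        """Trap separations spanning the requested unfolding-probability range,
        from the local sensitivity of the state-energy difference to D."""
        _, f1 = system_energy(self.folded, self.construct, self.traps, self.separation_half)
        _, f2 = system_energy(self.unfolded, self.construct, self.traps, self.separation_half)
        dgdd = (f1 - f2) / KBT_PN_NM  # kBT per nm of trap separation
        span = math.log(p_range[1] / (1 - p_range[1]))
        dd = span / dgdd
        return np.linspace(self.separation_half - dd, self.separation_half + dd, n)


def _build_domain(
    preset: str,
    domain: str,
    table: DomainTable,
    baseline_contour: float,
    baseline_h: float,
    handle: PolymerSegment = DEFAULT_HANDLE,
    stiffness: float = 0.1,
) -> TwoStateSystem:
    """Solve the preset construction: find the effective contour change,
    structured-extension change and equilibrium separation reproducing
    (f_half, delta_x, delta_g) in the series tether model."""
    traps = TrapSystem(effective_stiffness=stiffness)
    k = traps.effective_stiffness
    f1 = table.f_half + k * table.delta_x / 2.0  # folded-state force
    f2 = table.f_half - k * table.delta_x / 2.0  # unfolded-state force

    folded = FoldingState(
        name=f"{domain}_folded",
        unfolded_contour=baseline_contour,
        structured_extension=baseline_h,
        folding_energy=table.delta_g,
        zipper_position=table.zipper_folded,
    )
    construct0 = ConstructModel(states=(folded, folded), dna_handle=handle)
    d_star = state_extension(folded, construct0, f1) + f1 / k

    x_dna2 = wlc_extension(handle, f2)

    def h_unfolded(dl: float) -> float:
        pep = PolymerSegment(baseline_contour + dl, construct0.peptide_persistence)
        return d_star - f2 / k - wlc_extension(pep, f2) - x_dna2

    def unfolded_for(dl: float) -> FoldingState:
        h_u = h_unfolded(dl)
        return FoldingState(
            name=f"{domain}_unfolded",
            unfolded_contour=baseline_contour + dl,
            structured_extension=max(h_u, 0.0),
            folding_energy=0.0,
            zipper_position=table.zipper_unfolded,
        )

    def energy_residual(dl: float) -> float:
        unfolded = unfolded_for(dl)
        c = ConstructModel(states=(folded, unfolded), dna_handle=handle)
        g_f, _ = system_energy(folded, c, traps, d_star)
        g_u, _ = system_energy(unfolded, c, traps, d_star)
        return g_u - g_f

    # Largest admissible contour change: the unfolded structured extension
    # must stay non-negative.
    dl_hi = 60.0
    if h_unfolded(dl_hi) < 0:
        dl_hi = brentq(h_unfolded, 1e-3, dl_hi, xtol=1e-9) - 1e-6
    dl = brentq(energy_residual, 1e-3, dl_hi, xtol=1e-10)
    unfolded = unfolded_for(dl)
    construct = ConstructModel(states=(folded, unfolded), dna_handle=handle)

    sys = TwoStateSystem(
        preset=preset,
        domain=domain,
        table=table,
        folded=folded,
        unfolded=unfolded,
        ts=FoldingState("ts", 0.0, 0.0),  # placeholder, replaced below
        construct=construct,
        traps=traps,
        k_m=1.0,
        separation_half=d_star,
    )
    ts = sys.ts_state(table.g_ts, table.ts_fraction_from_folded)
    # Attempt rate from the equilibrium transition rate: at D*, both rates
    # equal rate_eq, so k_m = rate_eq * exp(+barrier at equilibrium).
    g_ts_sys, _ = system_energy(ts, construct, traps, d_star)
    g_f_sys, _ = system_energy(folded, construct, traps, d_star)
    k_m = table.rate_eq * math.exp(g_ts_sys - g_f_sys)

    return TwoStateSystem(
        preset=preset,
        domain=domain,
        table=table,
        folded=folded,
        unfolded=unfolded,
        ts=ts,
        construct=construct,
        traps=traps,
        k_m=k_m,
        separation_half=d_star,
    )


@dataclass(frozen=True)
class Preset:
    """Everything needed to emulate one SNARE complex in the instrument."""

    name: str
    ctd: TwoStateSystem
    ld: TwoStateSystem
    construct: ConstructModel  # five-state construct for pulling experiments
    traps: TrapSystem
    transient_probability: float
    transient_lifetime: float  # s
    ntd_unzip_force: tuple[float, float]  # (mean, SD) pN
    reassembly_force: float = REASSEMBLY_FORCE_PN

    @property
    def half_zipper_position(self) -> float:
        return self.ctd.table.zipper_unfolded


def make_preset(name: str, stiffness: float = 0.1) -> Preset:
    """Build the named preset (``neuronal``, ``glut4``, ``endosomal`` or
    ``yeast``) from the published two-state parameters."""
    if name not in PUBLISHED_PARAMS:
        raise KeyError(
            f"unknown preset {name!r}; choose from {', '.join(PRESET_NAMES)}"
        )
    tables = PUBLISHED_PARAMS[name]

    # LD transition first: its unfolded state is the baseline of the CTD
    # transition (state 2, LD open / CTD folded).
    ld = _build_domain(
        name, "ld", tables["ld"], BASELINE_CONTOUR_NM, H_FOLDED_NM, stiffness=stiffness
    )
    ctd = _build_domain(
        name,
        "ctd",
        tables["ctd"],
        ld.unfolded.unfolded_contour,
        ld.unfolded.structured_extension,
        stiffness=stiffness,
    )

    # Five-state construct for pulling cycles.  Energies are relative to the
    # half-zippered state; the t-SNARE intermediate sits approximately halfway
    # between the half-zippered and fully unfolded states in extension.
    s1 = FoldingState(
        "folded",
        ld.folded.unfolded_contour,
        ld.folded.structured_extension,
        ctd.table.delta_g + ld.table.delta_g,
        zipper_position=ld.table.zipper_folded,
    )
    s2 = FoldingState(
        "ld_open",
        ctd.folded.unfolded_contour,
        ctd.folded.structured_extension,
        ctd.table.delta_g,
        zipper_position=ctd.table.zipper_folded,
    )
    s3 = FoldingState(
        "half_zippered",
        ctd.unfolded.unfolded_contour,
        ctd.unfolded.structured_extension,
        0.0,
        zipper_position=ctd.table.zipper_unfolded,
    )
    s4 = FoldingState(
        "t_snare",
        s3.unfolded_contour + 0.5 * NTD_CONTOUR_NM,
        0.5 * s3.structured_extension,
        17.0,
        zipper_position=None,
    )
    s5 = FoldingState(
        "unfolded",
        s3.unfolded_contour + NTD_CONTOUR_NM,
        0.0,
        35.0,
        zipper_position=-24.0,
    )
    construct = ConstructModel(states=(s1, s2, s3, s4, s5))

    p_tr, tau_tr = TRANSIENT_INTERMEDIATE[name]
    return Preset(
        name=name,
        ctd=ctd,
        ld=ld,
        construct=construct,
        traps=TrapSystem(effective_stiffness=stiffness),
        transient_probability=p_tr,
        transient_lifetime=tau_tr,
        ntd_unzip_force=NTD_UNZIP_FORCE[name],
    )
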