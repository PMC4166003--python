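"""Simplified energy-landscape model of a two-state zippering transition.

The landscape on the contour-length reaction coordinate (0.365 nm per
unfolded amino acid) is characterised by four parameters: the free energy of
the folded state ``G_fold`` and of the transition state ``G_ts`` (both in
kBT, relative to the unfolded state), the transition-state position ``l_ts``
(amino acids C-terminal to the ionic layer), and a Kramers attempt rate
``k_m``.  At each trap separation the total system energy of the folded,
transition and unfolded states (folding energy + WLC entropic energies +
trap energy, see :mod:`snarefold.tether`) determines

    p        = 1 / (1 + exp(G_u_sys - G_f_sys))          (Boltzmann)
    k_unfold = k_m exp(-(G_ts_sys - G_f_sys))            (Kramers)
    k_fold   = k_m exp(-(G_ts_sys - G_u_sys))

so that k_unfold / k_fold == p / (1 - p) identically.  ``LandscapeModel``
fits these predictions to measured probability and rate scans by weighted
nonlinear least squares (lmfit); ``LandscapeResults`` carries the estimates,
uncertainties and diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import lmfit
import numpy as np
import pandas as pd

from .polymer import KBT_PN_NM, PolymerSegment, wlc_energy
from .presets import TwoStateSystem
from .tether import system_energy, system_energy_vector

__all__ = [
    "LandscapeParams",
    "WorkMeasurement",
    "SpacerCorrection",
    "landscape_predictions",
    "LandscapeModel",
    "LandscapeResults",
    "folding_energy_from_work",
    "spacer_correction",
    "average_segment_force",
]


@dataclass(frozen=True)
class LandscapeParams:
    """The four landscape parameters of one two-state transition."""

    g_fold: float  # kBT, folded-state energy (negative = stable)
    g_ts: float  # kBT, transition-state energy, relative to unfolded = 0
    l_ts_aa: float  # a.a. C-terminal to the ionic layer
    k_m: float  # 1/s, attempt rate

    def __post_init__(self) -> None:
        if self.k_m <= 0:
            raise ValueError("attempt rate k_m must be > 0")


def params_of_system(system: TwoStateSystem) -> LandscapeParams:
    """The landscape parameters a preset was constructed from."""
    t = system.table
    return LandscapeParams(t.delta_g, t.g_ts, t.ts_position_aa, system.k_m)


def _ts_fraction(system: TwoStateSystem, l_ts_aa: float) -> float:
    t = system.table
    return (t.zipper_folded - l_ts_aa) / (t.zipper_folded - t.zipper_unfolded)


def landscape_predictions(
    params: LandscapeParams,
    system: TwoStateSystem,
    separations,
) -> pd.DataFrame:
    """Per-separation predictions of the landscape model.

    Returns a frame with columns ``separation``, ``p`` (unfolding
    probability), ``k_fold``, ``k_unfold`` (1/s), the two state forces
    ``f1`` (folded), ``f2`` (unfolded), their mean ``f_mean`` and the
    constant-separation extension change ``delta_x``.
    """
    folded = replace(system.folded, folding_energy=params.g_fold)
    unfolded = replace(system.unfolded, folding_energy=0.0)
    ts = system.ts_state(params.g_ts, _ts_fraction(system, params.l_ts_aa))
    construct, traps = system.construct, system.traps
    k = traps.effective_stiffness

    d = np.atleast_1d(np.asarray(separations, dtype=float))
    g_f, f1 = system_energy_vector(folded, construct, traps, d)
    g_u, f2 = system_energy_vector(unfolded, construct, traps, d)
    g_t, _ = system_energy_vector(ts, construct, traps, d)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(g_u - g_f))
        k_unfold = params.k_m * np.exp(-(g_t - g_f))
        k_fold = params.k_m * np.exp(-(g_t - g_u))
    return pd.DataFrame(
        {
            "separation": d,
            "p": p,
            "k_unfold": k_unfold,
            "k_fold": k_fold,
            "f1": f1,
            "f2": f2,
            "f_mean": 0.5 * (f1 + f2),
            "delta_x": (f1 - f2) / k,
        }
    )


class LandscapeResults:
    """Estimates, uncertainties and diagnostics of a landscape fit."""

    def __init__(
        self,
        model: "LandscapeModel",
        minimizer_result: lmfit.minimizer.MinimizerResult,
    ) -> None:
        self.model = model
        self.minimizer_result = minimizer_result
        v = minimizer_result.params.valuesdict()
        self.params = LandscapeParams(
            v["g_fold"], v["g_ts"], v["l_ts_aa"], 10.0 ** v["log10_km"]
        )
        self.stderr = {
            name: (minimizer_result.params[name].stderr)
            for name in ("g_fold", "g_ts", "l_ts_aa", "log10_km")
        }
        self.covar = getattr(minimizer_result, "covar", None)
        self.redchi = minimizer_result.redchi
        self.nfev = minimizer_result.nfev
        self.flags: list[str] = []
        if self.covar is not None and np.all(np.isfinite(self.covar)):
            cond = np.linalg.cond(self.covar)
            if cond > 1e12:
                self.flags.append("ill-conditioned")
        else:
            self.flags.append("no-covariance")

    @property
    def g_fold(self) -> float:
        return self.params.g_fold

    @property
    def g_ts(self) -> float:
        return self.params.g_ts

    @property
    def l_ts_aa(self) -> float:
        return self.params.l_ts_aa

    @property
    def k_m(self) -> float:
        return self.params.k_m

    def predict(self, separations=None) -> pd.DataFrame:
        if separations is None:
            separations = self.model.data["separation"].to_numpy()
        return landscape_predictions(self.params, self.model.system, separations)

    def summary(self) -> str:
        lines = [
            "Two-state energy landscape fit",
            "=" * 46,
            f"preset/domain        {self.model.system.preset}/{self.model.system.domain}",
            f"n separations        {len(self.model.data)}",
            f"reduced chi^2        {self.redchi:.3g}",
        ]
        for label, name, unit in (
            ("folding energy", "g_fold", "kBT"),
            ("TS energy", "g_ts", "kBT"),
            ("TS position", "l_ts_aa", "a.a."),
        ):
            err = self.stderr[name]
            err_s = f" +/- {err:.2g}" if err is not None else ""
            val = getattr(self, name)
            lines.append(f"{label:<20} {val:8.2f}{err_s}  {unit}")
        lines.append(f"{'attempt rate':<20} {self.k_m:8.3g}  1/s")
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<LandscapeResults g_fold={self.g_fold:.2f} kBT>"


class LandscapeModel:
    """Weighted least-squares fit of the landscape model to a measured scan.

    Parameters
    ----------
    data : DataFrame
        One row per trap separation with columns ``separation``, ``p``,
        ``k_fold``, ``k_unfold`` and (optionally) ``n_transitions`` used for
        the statistical weights.  Binomial weights apply to logit(p),
        Poisson-count weights to the log rates.
    system : TwoStateSystem
        The mechanical two-state system (geometry, handle, traps); only the
        four landscape parameters are fitted.
    """

    _P_CLIP = 1e-4

    def __init__(self, data: pd.DataFrame, system: TwoStateSystem) -> None:
        required = {"separation", "p", "k_fold", "k_unfold"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"scan data missing columns: {sorted(missing)}")
        if len(data) < 3:
            raise ValueError("need at least three separations to fit")
        self.data = data.sort_values("separation").reset_index(drop=True)
        self.system = system

    # -- residuals ---------------------------------------------------------
    def _residuals(self, params: lmfit.Parameters) -> np.ndarray:
        v = params.valuesdict()
        lp = LandscapeParams(v["g_fold"], v["g_ts"], v["l_ts_aa"], 10.0 ** v["log10_km"])
        pred = landscape_predictions(lp, self.system, self.data["separation"].to_numpy())
        p_obs = np.clip(self.data["p"].to_numpy(), self._P_CLIP, 1 - self._P_CLIP)
        p_mod = np.clip(pred["p"].to_numpy(), self._P_CLIP, 1 - self._P_CLIP)
        n = self.data.get("n_transitions", pd.Series(np.full(len(p_obs), 100.0)))
        n = np.maximum(np.asarray(n, dtype=float), 2.0)
        w_p = np.sqrt(n * p_obs * (1 - p_obs))
        r_p = (np.log(p_obs / (1 - p_obs)) - np.log(p_mod / (1 - p_mod))) * w_p
        w_k = np.sqrt(n)
        r_ku = (
            np.log(self.data["k_unfold"].to_numpy() / pred["k_unfold"].to_numpy())
        ) * w_k
        r_kf = (
            np.log(self.data["k_fold"].to_numpy() / pred["k_fold"].to_numpy())
        ) * w_k
        return np.concatenate([r_p, r_ku, r_kf])

    def _start_params(self, frac_ts: float) -> lmfit.Parameters:
        t = self.system.table
        params = lmfit.Parameters()
        # Start the folding energy at the crude work estimate f1/2 * dX.
        params.add("g_fold", value=-abs(t.f_half * t.delta_x / KBT_PN_NM), min=-80.0, max=-0.5)
        params.add("g_ts", value=0.0, min=-25.0, max=40.0)
        l_lo = min(t.zipper_folded, t.zipper_unfolded)
        l_hi = max(t.zipper_folded, t.zipper_unfolded)
        span = l_hi - l_lo
        params.add(
            "l_ts_aa",
            value=l_hi - frac_ts * span,
            min=l_lo + 0.02 * span,
            max=l_hi - 0.02 * span,
        )
        params.add("log10_km", value=5.0, min=2.0, max=9.0)
        return params

    def fit(self, starts: tuple[float, ...] = (0.25, 0.5, 0.75)) -> LandscapeResults:
        """Fit by Levenberg-Marquardt least squares from a fixed multi-start
        grid over the transition-state position; deterministic given data."""
        best = None
        for frac in starts:
            res = lmfit.minimize(
                self._residuals, self._start_params(frac), method="leastsq"
            )
            if best is None or res.chisqr < best.chisqr:
                best = res
        return LandscapeResults(self, best)


# ---------------------------------------------------------------------------
# Work-based energies, spacer correction, segment-average forces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorkMeasurement:
    """Inputs of the reversible-work estimate of a folding energy."""

    f_half: float  # pN
    delta_x_total: float  # nm, extension change of the whole tether
    delta_l: float  # nm, contour change of the unfolded polypeptide
    delta_x_peptide: float  # nm, extension change of the unfolded polypeptide

    def __post_init__(self) -> None:
        if self.delta_x_total <= 0:
            raise ValueError("delta_x_total must be > 0")
        if not (0 <= self.delta_x_peptide < self.delta_l or self.delta_l == 0):
            raise ValueError("require 0 <= delta_x_peptide/delta_l < 1")


def folding_energy_from_work(
    m: WorkMeasurement,
    persistence_length: float = 0.6,
    kbt: float = KBT_PN_NM,
) -> float:
    """Unfolding free energy (kBT) from the mechanical work to reversibly
    unfold: ``f_half * dX - E(dl, dx/dl)`` with E the WLC entropic energy."""
    work = m.f_half * m.delta_x_total / kbt
    if m.delta_l == 0:
        return work
    seg = PolymerSegment(m.delta_l, persistence_length)
    return work - wlc_energy(seg, m.delta_x_peptide / m.delta_l, kbt)


@dataclass(frozen=True)
class SpacerCorrection:
    g_app: float  # kBT, apparent folding energy from the measurement
    g_sp: float  # kBT, spacer free-energy change on folding
    @property
    def g_corrected(self) -> float:
        return self.g_app - self.g_sp


def spacer_correction(
    g_app: float,
    folded_geometry: tuple[float, float] | None = None,
    unfolded_geometry: tuple[float, float] | None = None,
    g_sp: float | None = None,
    persistence_length: float = 0.6,
) -> SpacerCorrection:
    """Correct an apparent folding energy for the chimera spacer sequence.

    The spacer is a WLC whose (contour, endpoint distance) differ between the
    folded and unfolded states of the transition; its free-energy change
    ``G_sp = E(folded) - E(unfolded)`` contaminates the apparent energy:
    ``G_true = G_app - G_sp``.  Pass the two (contour nm, distance nm)
    geometries, or a precomputed ``g_sp``.
    """
    if g_sp is None:
        if folded_geometry is None or unfolded_geometry is None:
            raise ValueError("provide both geometries or g_sp")
        for l, x in (folded_geometry, unfolded_geometry):
            if x >= l:
                raise ValueError("endpoint distance must be below the contour")
        ef = wlc_energy(
            PolymerSegment(folded_geometry[0], persistence_length),
            folded_geometry[1] / folded_geometry[0],
        )
        eu = wlc_energy(
            PolymerSegment(unfolded_geometry[0], persistence_length),
            unfolded_geometry[1] / unfolded_geometry[0],
        )
        g_sp = ef - eu
    return SpacerCorrection(g_app=g_app, g_sp=g_sp)


def average_segment_force(
    total_energy: float,
    total_extension: float,
    segment_fraction: float,
    energy_fraction: float,
    kbt: float = KBT_PN_NM,
) -> float:
    """Average zippering force (pN) over a segment of the landscape.

    The average force over a region is the slope of the chord through the
    energy points at its two ends — independent of the landscape's interior
    shape: ``(energy_fraction * E_total * kBT) / (segment_fraction * dX)``.
    ``total_energy`` is in kBT, ``total_extension`` in nm.
    """
    if not (0 < segment_fraction <= 1) or not (0 < energy_fraction <= 1):
        raise ValueError("fractions must lie in (0, 1]")
    if total_extension <= 0:
        raise ValueError("total_extension must be > 0")
    return (energy_fraction * total_energy * kbt) / (
        segment_fraction * total_extension
    )
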