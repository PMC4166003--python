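"""Worm-like chain elasticity for the stretched elements of a protein-DNA tether.

Every stretched element of the dumbbell assay — the double-stranded DNA handle
and the unfolded polypeptide — is modelled as an inextensible worm-like chain
(WLC) characterised by its contour length ``l`` (nm) and persistence length
``P`` (nm).  The force-extension relation is the Marko-Siggia interpolation

    F(r) = (kBT / P) * [ 1 / (4 (1 - r)^2) + r - 1/4 ],    r = x / l,

accurate to a few percent over the full extension range, and the entropic
stretching energy is its closed-form integral

    E(l, r) = (kBT l / 4 P) * (3 r^2 - 2 r^3) / (1 - r).

Units are pN, nm and kBT = 4.1 pN nm (room temperature) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Thermal energy at room temperature, pN nm.
KBT_PN_NM = 4.1

#: Contour length gained per unfolded amino acid, nm.
NM_PER_AA = 0.365

#: B-form DNA helical rise per base pair, nm.
NM_PER_BP = 0.34

_R_MAX = 1.0 - 1e-9


@dataclass(frozen=True)
class PolymerSegment:
    """A worm-like chain element: DNA handle or unfolded polypeptide.

    Parameters
    ----------
    contour_length : float
        Contour length ``l`` in nm.  Zero is allowed as the degenerate
        fully-folded limit (the segment then contributes no extension and
        no energy).
    persistence_length : float
        Persistence length ``P`` in nm (0.6 nm for polypeptide, 30-50 nm
        for double-stranded DNA).
    """

    contour_length: float
    persistence_length: float

    def __post_init__(self) -> None:
        if self.contour_length < 0:
            raise ValueError(f"contour_length must be >= 0, got {self.contour_length}")
        if self.persistence_length <= 0:
            raise ValueError(
                f"persistence_length must be > 0, got {self.persistence_length}"
            )


def wlc_force_ratio(persistence_length: float, r, kbt: float = KBT_PN_NM):
    """Marko-Siggia force (pN) at fractional extension ``r = x / l``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 1):
        raise ValueError("fractional extension must satisfy 0 <= r < 1")
    out = (kbt / persistence_length) * (0.25 / (1.0 - r) ** 2 + r - 0.25)
    return out if out.ndim else float(out)


def wlc_force(segment: PolymerSegment, extension, kbt: float = KBT_PN_NM):
    """Force (pN) required to hold ``segment`` at ``extension`` (nm).

    Raises ``ValueError`` for negative extensions or extensions at or beyond
    the contour length, where the inextensible WLC diverges.
    """
    x = np.asarray(extension, dtype=float)
    if np.any(x < 0):
        raise ValueError("extension must be non-negative")
    if segment.contour_length == 0:
        if np.any(x > 0):
            raise ValueError("zero-contour segment cannot be extended")
        out = np.zeros_like(x)
        return out if out.ndim else 0.0
    if np.any(x >= segment.contour_length):
        raise ValueError("extension must be below the contour length")
    return wlc_force_ratio(segment.persistence_length, x / segment.contour_length, kbt)


def inverse_wlc_ratio(persistence_length: float, force, kbt: float = KBT_PN_NM):
    """Fractional extension ``r`` at which the Marko-Siggia force equals
    ``force`` (pN): damped-Newton inverse, clipped to [0, 1), converged to
    machine precision (the target function is smooth, increasing and convex,
    with slope >= 1 in the reduced variable)."""
    phi = np.asarray(force, dtype=float) * persistence_length / kbt
    if np.any(phi < 0):
        raise ValueError("force must be non-negative")
    # high-force asymptote as the start; clipping keeps iterates in range
    r = np.clip(1.0 - 0.5 / np.sqrt(phi + 0.5), 0.0, _R_MAX)
    for _ in range(60):
        g = 0.25 / (1.0 - r) ** 2 + r - 0.25 - phi
        dg = 0.5 / (1.0 - r) ** 3 + 1.0
        step = g / dg
        r = np.clip(r - step, 0.0, _R_MAX)
        if np.all(np.abs(step) < 1e-15):
            break
    return r if r.ndim else float(r)


def wlc_extension(segment: PolymerSegment, force, kbt: float = KBT_PN_NM):
    """Extension (nm) of ``segment`` under ``force`` (pN): numerical inverse
    of the Marko-Siggia relation on r in [0, 1)."""
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    if segment.contour_length == 0:
        out = np.zeros_like(f)
        return out if out.ndim else 0.0
    r = inverse_wlc_ratio(segment.persistence_length, f, kbt)
    out = r * segment.contour_length
    return out if np.ndim(out) else float(out)


def wlc_energy(segment: PolymerSegment, r, kbt: float = KBT_PN_NM):
    """Entropic stretching energy (kBT) of ``segment`` at fractional
    extension ``r``: closed-form integral of the Marko-Siggia force."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 1):
        raise ValueError("fractional extension must satisfy 0 <= r < 1")
    out = (
        segment.contour_length
        / (4.0 * segment.persistence_length)
        * (3.0 * r**2 - 2.0 * r**3)
        / (1.0 - r)
    )
    return out if out.ndim else float(out)


def flory_residual_extension(segment: PolymerSegment) -> float:
    """Residual end-to-end extension (nm) of an unstretched chain grafted to
    a surface: half the Flory radius of a semi-flexible chain,
    ``l^(3/5) P^(2/5) / 2``."""
    return (
        segment.contour_length ** 0.6 * segment.persistence_length ** 0.4 / 2.0
    )
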