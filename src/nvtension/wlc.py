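"""Worm-like-chain mechanics of the PEG tether.

The tension sensor transduces force through a short PEG chain (MW ~1000
g/mol) anchored to the diamond surface, with the paramagnetic label at its
free end. Chain elasticity is modelled with the Marko–Siggia interpolation
of the worm-like chain,

    F(x) = (kB*T / Lp) * [ 1/(4 (1 - x/Lc)^2) - 1/4 + x/Lc ],

optionally extended with an enthalpic stretch modulus K0 via the substitution
x/Lc -> x/Lc - F/K0 solved self-consistently. All lengths are in nm, forces
in pN, temperatures in K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KB_PN_NM_PER_K",
    "PEG_MONOMER_MASS",
    "PEG_MONOMER_LENGTH_BOUNDS",
    "PolymerParams",
    "wlc_force",
    "wlc_extension",
    "contour_length_bounds",
    "sensitive_force_range",
]

#: Boltzmann constant in pN·nm/K (kB*T ≈ 4.114 pN·nm at 298 K).
KB_PN_NM_PER_K = 0.01380649

#: Mass of one ethylene-oxide repeat unit (g/mol).
PEG_MONOMER_MASS = 44.05

#: Effective per-monomer contour-length bounds (nm). Back-derived so that a
#: MW ~1000 g/mol chain spans a full contour length of 6.20–7.98 nm; these
#: are working assumptions, not measured helix geometries.
PEG_MONOMER_LENGTH_BOUNDS = (0.273, 0.352)


@dataclass(frozen=True)
class PolymerParams:
    """Elastic parameters of the tether.

    Parameters
    ----------
    contour_length : float
        Full contour length Lc (nm).
    persistence_length : float
        Persistence length Lp (nm); must satisfy 0 < Lp < Lc.
    temperature : float
        Absolute temperature (K).
    stretch_modulus : float or None
        Enthalpic stretch modulus K0 (pN). ``None`` (default) means the
        inextensible Marko–Siggia limit (K0 -> infinity).
    """

    contour_length: float = 7.98
    persistence_length: float = 0.38
    temperature: float = 298.0
    stretch_modulus: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.persistence_length < self.contour_length:
            raise ValueError(
                "require 0 < persistence_length < contour_length, got "
                f"Lp={self.persistence_length}, Lc={self.contour_length}"
            )
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.stretch_modulus is not None and self.stretch_modulus <= 0:
            raise ValueError("stretch_modulus must be positive or None")

    @property
    def kbt(self) -> float:
        """Thermal energy kB*T in pN·nm."""
        return KB_PN_NM_PER_K * self.temperature


def _ms_force_scalar(x: float, params: PolymerParams) -> float:
    lc = params.contour_length
    pref = params.kbt / params.persistence_length
    if params.stretch_modulus is None:
        if x < 0 or x >= lc:
            raise ValueError(f"extension must lie in [0, Lc), got x={x}, Lc={lc}")
        frac = x / lc
        return pref * (0.25 / (1.0 - frac) ** 2 - 0.25 + frac)
    # Extensible chain: solve F = f(x/Lc - F/K0) self-consistently. The
    # effective fractional extension must stay below 1, which brackets F.
    k0 = params.stretch_modulus
    if x < 0:
        raise ValueError(f"extension must be non-negative, got {x}")

    def resid(force: float) -> float:
        frac = x / lc - force / k0
        return pref * (0.25 / (1.0 - frac) ** 2 - 0.25 + frac) - force

    # resid is strictly decreasing in F (raising F slackens the effective
    # fractional extension), so bracket downward from lo.
    lo = 0.0
    if x / lc >= 1.0:  # force must at least pull frac back below 1
        lo = (x / lc - 1.0) * k0 * (1 + 1e-12) + 1e-9
    if resid(lo) <= 0:
        return float(lo)
    hi = max(2.0 * lo, 1.0)
    while resid(hi) > 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - pathological parameters
            raise RuntimeError("failed to bracket extensible WLC force")
    return brentq(resid, lo, hi, xtol=1e-14, rtol=1e-14)


def wlc_force(extension, params: PolymerParams | None = None):
    """Force (pN) required to hold the chain at a given extension (nm).

    Accepts a scalar or array extension. For the inextensible chain the
    extension must satisfy 0 <= x < Lc; the force diverges as x -> Lc.
    """
    params = params or PolymerParams()
    x = np.asarray(extension, dtype=float)
    if x.ndim == 0:
        return _ms_force_scalar(float(x), params)
    out = np.empty(x.shape, dtype=float)
    flat = x.ravel()
    res = out.ravel()
    for i, xi in enumerate(flat):
        res[i] = _ms_force_scalar(float(xi), params)
    return out


def wlc_extension(force, params: PolymerParams | None = None, rtol: float = 1e-9):
    """Extension (nm) at a given force (pN): numeric inverse of :func:`wlc_force`.

    Uses bracketed root finding on [0, Lc); the forward-inverse round trip
    closes to better than 1e-6 relative across the valid domain.
    """
    params = params or PolymerParams()
    lc = params.contour_length

    def invert(f: float) -> float:
        if f < 0:
            raise ValueError(f"force must be non-negative, got {f}")
        if f == 0.0:
            return 0.0
        hi = lc * (1.0 - 1e-12)
        while _ms_force_scalar(hi, params) < f:  # extensible chains exceed Lc
            hi = lc + 2 * (hi - lc) + lc * 1e-6 if hi >= lc else lc * 1.001
            if hi > 100 * lc:  # pragma: no cover
                raise RuntimeError("failed to bracket extension")
        root = brentq(
            lambda x: _ms_force_scalar(x, params) - f,
            0.0,
            hi,
            xtol=1e-13,
            rtol=min(rtol, 1e-9),
            maxiter=200,
        )
        return root

    f = np.asarray(force, dtype=float)
    if f.ndim == 0:
        return invert(float(f))
    out = np.empty(f.shape, dtype=float)
    res = out.ravel()
    for i, fi in enumerate(f.ravel()):
        res[i] = invert(float(fi))
    return out


def contour_length_bounds(molecular_weight: float) -> tuple[float, float]:
    """Bounds on the full contour length (nm) of a PEG of given MW (g/mol).

    The chain is MW / 44.05 ethylene-oxide monomers; each contributes
    0.273–0.352 nm of contour depending on the assumed backbone geometry,
    so a MW 1000 chain spans 6.20–7.98 nm.
    """
    if molecular_weight < PEG_MONOMER_MASS:
        raise ValueError(
            f"molecular weight must be at least one monomer ({PEG_MONOMER_MASS} g/mol)"
        )
    n = molecular_weight / PEG_MONOMER_MASS
    lo, hi = PEG_MONOMER_LENGTH_BOUNDS
    return (n * lo, n * hi)


def sensitive_force_range(
    params: PolymerParams,
    calibration,
    threshold: float = 0.1,
    force_grid=None,
):
    """Force interval over which the sensor responds appreciably.

    Composes the transduction chain T1(F) = calibration(h = x(F)) and finds
    the contiguous interval of forces where |dT1/dF| exceeds ``threshold``
    times its maximum. ``calibration`` is a
    :class:`~nvtension.spin_bath.CalibrationTable` (or any object with
    ``height_to_t1`` and ``h_min``/``h_max`` attributes).

    Returns
    -------
    (f_low, f_high) : tuple of float, in pN, or ``None`` if the interval is
    empty at the requested threshold.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    h_lo = getattr(calibration, "h_min")
    h_hi = getattr(calibration, "h_max")
    f_lo = wlc_force(min(h_lo, params.contour_length * 0.999), params)
    f_hi = wlc_force(min(h_hi, params.contour_length * 0.999), params)
    if force_grid is None:
        force_grid = np.linspace(f_lo, f_hi, 400)
    forces = np.asarray(force_grid, dtype=float)
    exts = wlc_extension(forces, params)
    t1 = calibration.height_to_t1(np.clip(exts, h_lo, h_hi))
    dt1_df = np.gradient(t1, forces)
    sens = np.abs(dt1_df)
    cut = threshold * sens.max()
    ok = sens >= cut
    if not ok.any():
        return None
    idx = np.flatnonzero(ok)
    return (float(forces[idx[0]]), float(forces[idx[-1]]))
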