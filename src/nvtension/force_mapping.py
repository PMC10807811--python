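"""Inversion of T1 maps into PEG-extension and normal-force maps.

A measured pixel T1 is converted to a Gd-label height through the inverse of
the height->T1 calibration; the height is identified with the vertical
extension of the tether (configurable offset h0, default 0), and extension is
converted to force through the worm-like-chain law. Pixels are classified:

* ``compressed``  — T1 below the relaxed-sensor reference (410 us): the
  tether is pushed toward the surface; extension is reported but the
  entropic-spring force law does not apply, so force is NaN.
* ``in_range``    — reference <= T1 <= calibration maximum: full inversion.
* ``above_range`` — T1 beyond the calibrated range (or extension >= Lc):
  clamped, flagged, no force.
* ``unconverged`` — the pixel fit failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .fitting import T1Map
from .spin_bath import CalibrationTable
from .wlc import PolymerParams, wlc_force

__all__ = [
    "PixelClass",
    "ForceMap",
    "t1_to_height",
    "classify_pixel",
    "classify",
    "force_map",
    "line_profile",
]

DEFAULT_REFERENCE_T1_US = 410.0
DEFAULT_T1_RANGE_US = (391.0, 795.0)


class PixelClass(IntEnum):
    IN_RANGE = 0
    COMPRESSED = 1
    ABOVE_RANGE = 2
    UNCONVERGED = 3


def t1_to_height(t1, calibration: CalibrationTable):
    """Invert the calibration table (monotone PCHIP); out-of-range values are
    boundary-clamped and flagged. Returns (height_nm, clamped_mask)."""
    return calibration.t1_to_height(t1)


def classify_pixel(
    t1_us: float,
    reference_t1_us: float = DEFAULT_REFERENCE_T1_US,
    t1_range_us: tuple[float, float] = DEFAULT_T1_RANGE_US,
    converged: bool = True,
) -> PixelClass:
    """Classify one pixel from its fitted T1.

    Below the reference the tether is being compressed; above the calibrated
    range the sensor has saturated. Ties at the reference count as in_range.
    """
    if not t1_range_us[0] <= t1_range_us[1]:
        raise ValueError("T1 range must be ordered")
    if not converged or not np.isfinite(t1_us):
        return PixelClass.UNCONVERGED
    if t1_us < reference_t1_us:
        return PixelClass.COMPRESSED
    if t1_us > t1_range_us[1]:
        return PixelClass.ABOVE_RANGE
    return PixelClass.IN_RANGE


def classify(
    t1: np.ndarray,
    converged: np.ndarray | None = None,
    reference_t1_us: float = DEFAULT_REFERENCE_T1_US,
    t1_range_us: tuple[float, float] = DEFAULT_T1_RANGE_US,
) -> np.ndarray:
    """Vectorized :func:`classify_pixel`; returns an int array of PixelClass."""
    if not t1_range_us[0] <= t1_range_us[1]:
        raise ValueError("T1 range must be ordered")
    t1 = np.asarray(t1, dtype=float)
    if converged is None:
        converged = np.isfinite(t1)
    out = np.full(t1.shape, int(PixelClass.IN_RANGE), dtype=np.int8)
    out[t1 < reference_t1_us] = int(PixelClass.COMPRESSED)
    out[t1 > t1_range_us[1]] = int(PixelClass.ABOVE_RANGE)
    out[~(np.asarray(converged, bool) & np.isfinite(t1))] = int(PixelClass.UNCONVERGED)
    return out


@dataclass
class ForceMap:
    """Per-pixel tether extension (nm) and normal force (pN).

    ``force`` is finite only where ``pixel_class == IN_RANGE``; ``extension``
    is reported for every converged pixel (clamped at the calibration
    boundaries where flagged). ``provenance`` records the calibration and
    polymer parameters used.
    """

    extension_nm: np.ndarray
    force_pn: np.ndarray
    pixel_class: np.ndarray
    clamped: np.ndarray
    pixel_size_nm: float
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.extension_nm.shape

    def class_counts(self) -> dict[str, int]:
        return {
            cls.name.lower(): int(np.sum(self.pixel_class == int(cls)))
            for cls in PixelClass
        }


def force_map(
    t1map: T1Map,
    calibration: CalibrationTable,
    polymer: PolymerParams | None = None,
    reference_t1_us: float = DEFAULT_REFERENCE_T1_US,
    t1_range_us: tuple[float, float] | None = None,
    h0_nm: float = 0.0,
) -> ForceMap:
    """Convert a T1 map into extension and force maps with classification.

    Extension follows the convention x = h - h0 with the label height h from
    the inverted calibration (default h0 = 0, i.e. extension equals height).
    Force is evaluated only for in-range pixels; an extension at or beyond
    the contour length flags the pixel as above_range instead of raising.
    """
    polymer = polymer or PolymerParams()
    if t1_range_us is None:
        t1_range_us = (calibration.t1_min, calibration.t1_max)
    heights, clamped = calibration.t1_to_height(t1map.t1)
    heights = np.asarray(heights, dtype=float)
    extension = heights - h0_nm
    classes = classify(t1map.t1, t1map.converged, reference_t1_us, t1_range_us)

    overlong = (extension >= polymer.contour_length) & (classes == int(PixelClass.IN_RANGE))
    classes[overlong] = int(PixelClass.ABOVE_RANGE)
    extension = np.minimum(extension, polymer.contour_length)
    unconv = classes == int(PixelClass.UNCONVERGED)
    extension[unconv] = np.nan

    force = np.full(extension.shape, np.nan)
    sel = classes == int(PixelClass.IN_RANGE)
    if sel.any():
        force[sel] = wlc_force(extension[sel], polymer)

    return ForceMap(
        extension_nm=extension,
        force_pn=force,
        pixel_class=classes,
        clamped=np.asarray(clamped, bool) | overlong,
        pixel_size_nm=t1map.pixel_size_nm,
        provenance={
            "calibration": dict(calibration.metadata),
            "h_range_nm": [calibration.h_min, calibration.h_max],
            "t1_range_us": list(t1_range_us),
            "reference_t1_us": reference_t1_us,
            "polymer": {
                "contour_length": polymer.contour_length,
                "persistence_length": polymer.persistence_length,
                "temperature": polymer.temperature,
                "stretch_modulus": polymer.stretch_modulus,
            },
            "h0_nm": h0_nm,
        },
    )


def line_profile(fmap: ForceMap, start_px, end_px, n_samples: int = 100):
    """Sample force and extension along a line between two pixel coordinates.

    Bilinear interpolation; NaN propagates through pixels without force.
    Returns a pandas DataFrame (distance_nm, extension_nm, force_pN) ready
    for CSV export — the analogue of a drawn line profile across a cell map.
    """
    import pandas as pd
    from scipy.ndimage import map_coordinates

    start = np.asarray(start_px, dtype=float)
    end = np.asarray(end_px, dtype=float)
    t = np.linspace(0.0, 1.0, n_samples)
    rows = start[0] + t * (end[0] - start[0])
    cols = start[1] + t * (end[1] - start[1])
    coords = np.vstack([rows, cols])
    dist = np.hypot(rows - rows[0], cols - cols[0]) * fmap.pixel_size_nm
    force = map_coordinates(fmap.force_pn, coords, order=1, cval=np.nan)
    ext = map_coordinates(fmap.extension_nm, coords, order=1, cval=np.nan)
    return pd.DataFrame(
        {"distance_nm": dist, "extension_nm": ext, "force_pN": force}
    )
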