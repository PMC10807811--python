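"""Synthetic widefield relaxometry experiments.

Stands in for the microscope: builds cell-like adhesion force fields
(edge-concentrated traction around a footprint), forward-models them through
the tether mechanics and the height->T1 calibration into a T1 field, and
renders paired MW-on/MW-off photon-noise image stacks that the fitting
pipeline can consume. Every stack embeds its generating ground truth so
recovery tests never re-derive truth from outputs.

Frame model: with e(tau) = exp(-(tau/T1)^b) the per-pixel recovery contrast,

    on(tau)  = I0 * (c + a * (1 - e)),
    off(tau) = on(tau) * (c + a * e),

so the element-wise division off/on equals c + a*e exactly — the stretched
exponential the fitting stage assumes. Poisson shot noise is applied per
pixel per frame. Real instruments' off channel is itself a decaying trace
and the ratio is only approximately stretched-exponential; this generator
makes the cancellation exact so pipeline tests close to fit tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

from .fitting import WidefieldStack
from .force_mapping import DEFAULT_REFERENCE_T1_US, classify
from .spin_bath import CalibrationTable
from .wlc import PolymerParams, wlc_extension

__all__ = [
    "ForceField",
    "SyntheticTruth",
    "make_cell_force_field",
    "forward_t1_field",
    "render_widefield_stack",
]


@dataclass
class ForceField:
    """Cell-like traction force pattern on a pixel grid.

    ``force_pn`` is zero outside ``mask`` and non-negative inside; ``params``
    records the generator parameters (footprint, band, forces, noise, seed).
    """

    force_pn: np.ndarray
    mask: np.ndarray
    pixel_size_nm: float
    params: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.force_pn.shape


def _ellipse_mask(shape, pixel_size_nm, center_nm, semi_axes_nm, angle_deg=0.0):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    x = (xx + 0.5) * pixel_size_nm - center_nm[0]
    y = (yy + 0.5) * pixel_size_nm - center_nm[1]
    th = np.deg2rad(angle_deg)
    xr = x * np.cos(th) + y * np.sin(th)
    yr = -x * np.sin(th) + y * np.cos(th)
    return (xr / semi_axes_nm[0]) ** 2 + (yr / semi_axes_nm[1]) ** 2 <= 1.0


def _polygon_mask(shape, pixel_size_nm, vertices_nm):
    from matplotlib.path import Path

    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack(
        [(xx.ravel() + 0.5) * pixel_size_nm, (yy.ravel() + 0.5) * pixel_size_nm]
    )
    return Path(np.asarray(vertices_nm, float)).contains_points(pts).reshape(h, w)


def make_cell_force_field(
    shape: tuple[int, int] = (64, 64),
    pixel_size_nm: float = 96.0,
    footprint: str = "ellipse",
    center_nm: tuple[float, float] | None = None,
    semi_axes_nm: tuple[float, float] | None = None,
    angle_deg: float = 0.0,
    vertices_nm=None,
    edge_band_nm: float = 480.0,
    interior_force_pn: float = 8.0,
    edge_force_pn: float = 25.0,
    n_lobes: int = 0,
    lobe_gain: float = 0.0,
    noise_sd_pn: float = 0.0,
    seed=None,
) -> ForceField:
    """Generate an edge-concentrated adhesion force field.

    The footprint (ellipse by default, or a polygon via ``vertices_nm``)
    carries ``interior_force_pn`` inside and ``edge_force_pn`` in a band of
    width ``edge_band_nm`` along its rim — emulating traction concentrated at
    the cell periphery. Optional polarized lobes multiply the edge force by
    ``1 + lobe_gain * cos(n_lobes * phi)^2``. Gaussian noise (sd in pN) is
    added inside the mask and clipped at zero; the mask geometry itself is
    deterministic given the parameters, so two seeds differ only in noise.
    """
    if not (edge_force_pn >= interior_force_pn >= 0):
        raise ValueError("require edge_force >= interior_force >= 0")
    if edge_band_nm <= 0:
        raise ValueError("edge band width must be positive")
    h, w = shape
    extent = (w * pixel_size_nm, h * pixel_size_nm)
    if center_nm is None:
        center_nm = (extent[0] / 2.0, extent[1] / 2.0)
    if footprint == "ellipse":
        if semi_axes_nm is None:
            semi_axes_nm = (0.35 * extent[0], 0.25 * extent[1])
        mask = _ellipse_mask(shape, pixel_size_nm, center_nm, semi_axes_nm, angle_deg)
    elif footprint == "polygon":
        if vertices_nm is None:
            raise ValueError("polygon footprint requires vertices_nm")
        mask = _polygon_mask(shape, pixel_size_nm, vertices_nm)
    else:
        raise ValueError(f"unknown footprint {footprint!r}")
    if not mask.any():
        raise ValueError("footprint does not intersect the grid")

    # Distance (nm) from each interior pixel to the footprint rim.
    dist_nm = distance_transform_edt(mask) * pixel_size_nm
    edge_band = mask & (dist_nm <= edge_band_nm)
    interior = mask & ~edge_band
    if not interior.any():
        raise ValueError("edge band is wider than the footprint; shrink edge_band_nm")

    force = np.zeros(shape, dtype=float)
    force[interior] = interior_force_pn
    force[edge_band] = edge_force_pn
    if n_lobes > 0 and lobe_gain > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        phi = np.arctan2(
            (yy + 0.5) * pixel_size_nm - center_nm[1],
            (xx + 0.5) * pixel_size_nm - center_nm[0],
        )
        force[edge_band] *= 1.0 + lobe_gain * np.cos(n_lobes * phi[edge_band] / 2.0) ** 2
    if noise_sd_pn > 0:
        rng = np.random.default_rng(seed)
        force[mask] = np.clip(force[mask] + rng.normal(0, noise_sd_pn, int(mask.sum())), 0, None)

    return ForceField(
        force_pn=force,
        mask=mask,
        pixel_size_nm=pixel_size_nm,
        params={
            "footprint": footprint,
            "center_nm": tuple(center_nm),
            "semi_axes_nm": tuple(semi_axes_nm) if semi_axes_nm is not None else None,
            "edge_band_nm": edge_band_nm,
            "interior_force_pn": interior_force_pn,
            "edge_force_pn": edge_force_pn,
            "n_lobes": n_lobes,
            "lobe_gain": lobe_gain,
            "noise_sd_pn": noise_sd_pn,
            "seed": seed,
        },
    )


@dataclass
class SyntheticTruth:
    """Ground truth carried by a synthetic experiment."""

    t1_us: np.ndarray
    force_pn: np.ndarray
    mask: np.ndarray
    saturated: np.ndarray
    true_class: np.ndarray
    reference_t1_us: float


def forward_t1_field(
    field: ForceField,
    polymer: PolymerParams | None = None,
    calibration: CalibrationTable | None = None,
    reference_t1_us: float = DEFAULT_REFERENCE_T1_US,
) -> SyntheticTruth:
    """Forward-model a force field into a per-pixel T1 field.

    Each loaded pixel maps F -> extension (WLC inverse) -> height -> T1
    (calibration). Zero-force and background pixels sit at the relaxed-sensor
    reference T1. Forces whose extension falls outside the calibrated height
    range are clamped and marked saturating. The true pixel class (as the
    classifier would see noiseless data) is embedded for recovery tests.
    """
    from .spin_bath import default_calibration

    polymer = polymer or PolymerParams()
    calibration = calibration or default_calibration()
    force = field.force_pn
    t1 = np.full(force.shape, float(reference_t1_us))
    saturated = np.zeros(force.shape, dtype=bool)

    loaded = force > 0
    if loaded.any():
        vals, inverse = np.unique(force[loaded], return_inverse=True)
        exts = np.array([wlc_extension(float(f), polymer) for f in vals])[inverse]
        saturated[loaded] = (exts < calibration.h_min) | (exts > calibration.h_max)
        t1[loaded] = calibration.height_to_t1(exts)

    true_class = classify(t1, reference_t1_us=reference_t1_us,
                          t1_range_us=(calibration.t1_min, calibration.t1_max))
    return SyntheticTruth(
        t1_us=t1,
        force_pn=force.copy(),
        mask=field.mask.copy(),
        saturated=saturated,
        true_class=true_class,
        reference_t1_us=reference_t1_us,
    )


def render_widefield_stack(
    t1_field: np.ndarray,
    tau_grid: np.ndarray,
    photons_per_pixel: float = 1e5,
    contrast_a: float = 0.1,
    contrast_c: float = 1.0,
    stretch_b=1.0,
    pixel_size_nm: float = 96.0,
    seed=None,
    shot_noise: bool = True,
    truth: SyntheticTruth | None = None,
) -> WidefieldStack:
    """Render a T1 field into a paired MW-on/MW-off photon-count stack.

    ``photons_per_pixel`` scales the nominal per-frame photon budget (the
    camera integrates tens of thousands of pulse-sequence repetitions per
    frame, so counts are large). ``stretch_b`` may be a scalar or a per-pixel
    array; the default 1 renders single-rate pixels. ``shot_noise=False``
    returns the noiseless frame means (the infinite-budget limit).
    """
    if photons_per_pixel <= 0:
        raise ValueError("photon budget must be positive")
    tau = np.asarray(tau_grid, dtype=float)
    if tau.size == 0:
        raise ValueError("tau schedule is empty")
    t1 = np.asarray(t1_field, dtype=float)
    if np.any(~np.isfinite(t1)) or np.any(t1 <= 0):
        raise ValueError("T1 field must be finite and positive")
    b = np.broadcast_to(np.asarray(stretch_b, dtype=float), t1.shape)

    e = np.exp(-((tau[:, None, None] / t1[None]) ** b[None]))
    on_mean = photons_per_pixel * (contrast_c + contrast_a * (1.0 - e))
    off_mean = on_mean * (contrast_c + contrast_a * e)
    if shot_noise:
        rng = np.random.default_rng(seed)
        on = rng.poisson(on_mean).astype(float)
        off = rng.poisson(off_mean).astype(float)
    else:
        on, off = on_mean, off_mean

    metadata = {
        "synthetic": True,
        "photons_per_pixel": photons_per_pixel,
        "contrast_a": contrast_a,
        "contrast_c": contrast_c,
        "stretch_b": np.asarray(stretch_b, dtype=float),
        "seed": seed,
        "shot_noise": shot_noise,
        "truth_t1_us": t1.copy(),
    }
    if truth is not None:
        metadata.update(
            truth_force_pn=truth.force_pn.copy(),
            truth_mask=truth.mask.copy(),
            truth_class=truth.true_class.copy(),
            truth_saturated=truth.saturated.copy(),
            reference_t1_us=truth.reference_t1_us,
        )
    return WidefieldStack(tau=tau, on=on, off=off,
                          pixel_size_nm=pixel_size_nm, metadata=metadata)
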