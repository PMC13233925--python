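"""Eccentricity-varying density models and two-dimensional density maps.

Densities of cones and of ON-center midget RGC receptive fields are specified
along the four principal visual-field meridians (0 deg = temporal, 90 =
superior, 180 = nasal, 270 = inferior, right eye) and interpolated bilinearly
in polar form (linearly along radius on the two flanking meridians, then
linearly in polar angle) to obtain a smooth 2D map in cells/deg^2.

The midget-RGC receptive-field density follows the parametric meridian
formula of Watson (2014); the ON-center mosaic is taken as half of the total
midget density at every point. The cone density uses the same parametric
basis against linear eccentricity (mm), approximating the Curcio et al.
(1990) human profiles with a configurable foveal peak (288,000 cones/mm^2 by
default). Coefficients are read from a versioned JSON config so that
alternative density models can be swapped in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .geometry import deg_to_mm_human, mm_per_deg_human

__all__ = [
    "MERIDIAN_ANGLES",
    "MeridianDensitySet",
    "DensityMap",
    "meridian_density",
    "build_density_map",
    "load_density_params",
]

MERIDIAN_ANGLES = {"temporal": 0.0, "superior": 90.0, "nasal": 180.0, "inferior": 270.0}
_ANGLE_ORDER = ["temporal", "superior", "nasal", "inferior"]
MAX_ECC_DEG = 40.0


def load_density_params() -> dict:
    with resources.files("midgetmosaic.data").joinpath("density_params.json").open() as fh:
        return json.load(fh)


def _basis(r, a, r2, re):
    return a * (1.0 + r / r2) ** -2 + (1.0 - a) * np.exp(-r / re)


@dataclass
class MeridianDensitySet:
    """Density along the four principal meridians for one cell class.

    ``cell_class`` is one of {"cone", "on_mrgc_rf"}. Calling the instance with
    an eccentricity (deg) and a meridian name returns density in cells/deg^2.
    """

    cell_class: str
    params: dict = field(default_factory=load_density_params)

    def __post_init__(self):
        if self.cell_class not in ("cone", "on_mrgc_rf"):
            raise ValueError(f"unknown cell_class {self.cell_class!r}")

    @property
    def peak_density_mm2(self) -> float:
        """Density (cells/mm^2) at zero eccentricity."""
        peak_deg2 = self(0.0, "temporal")
        return peak_deg2 / mm_per_deg_human(0.0) ** 2

    def __call__(self, ecc_deg, meridian: str):
        r = np.asarray(ecc_deg, dtype=float)
        if np.any(r < 0) or np.any(r > MAX_ECC_DEG):
            raise ValueError(f"eccentricity outside [0, {MAX_ECC_DEG}] deg")
        if meridian not in MERIDIAN_ANGLES:
            raise ValueError(f"unknown meridian {meridian!r}")
        if self.cell_class == "on_mrgc_rf":
            blk = self.params["mrgc_rf"]
            mp = blk["meridians"][meridian]
            total = (
                blk["peak_density_deg2"]
                / (1.0 + r / blk["rm_deg"])
                * _basis(r, mp["a"], mp["r2"], mp["re"])
            )
            return self.params["on_mrgc_fraction"] * total
        blk = self.params["cone"]
        mp = blk["meridians"][meridian]
        x_mm = deg_to_mm_human(r)
        dens_mm2 = blk["peak_density_mm2"] * _basis(x_mm, mp["a"], mp["r2"], mp["re"])
        return dens_mm2 * mm_per_deg_human(r) ** 2


def meridian_density(ecc_deg, meridian: str, cell_class: str, params: dict | None = None):
    """Density (cells/deg^2) at ``ecc_deg`` along a principal meridian.

    For ``cell_class='on_mrgc_rf'`` this is exactly half of the total
    midget-RGC receptive-field density.
    """
    kwargs = {} if params is None else {"params": params}
    return MeridianDensitySet(cell_class, **kwargs)(ecc_deg, meridian)


@dataclass
class DensityMap:
    """Target 2D density sampled on a rectangular grid of visual-field positions."""

    x_deg: np.ndarray  # (nx,)
    y_deg: np.ndarray  # (ny,)
    values: np.ndarray  # (ny, nx), cells/deg^2
    cell_class: str
    meridians: MeridianDensitySet | None = None

    def __call__(self, x, y):
        """Evaluate the density at arbitrary points.

        Uses the exact polar-interpolated model when the meridian set is
        attached, otherwise bilinear interpolation on the stored grid.
        """
        if self.meridians is not None:
            return _polar_density(self.meridians, x, y)
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (self.y_deg, self.x_deg), self.values, bounds_error=False, fill_value=None
        )
        pts = np.stack([np.broadcast_arrays(np.asarray(y, float), np.asarray(x, float))[0],
                        np.broadcast_arrays(np.asarray(y, float), np.asarray(x, float))[1]], axis=-1)
        return interp(pts)

    def integral(self, region: tuple[float, float, float, float], n: int = 201) -> float:
        """Integral of the density over ``region = (x0, x1, y0, y1)`` (cells)."""
        x0, x1, y0, y1 = region
        xs = np.linspace(x0, x1, n)
        ys = np.linspace(y0, y1, n)
        xx, yy = np.meshgrid(xs, ys)
        vals = self(xx, yy)
        return float(np.trapezoid(np.trapezoid(vals, xs, axis=1), ys))


def _polar_density(mset: MeridianDensitySet, x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    quad = np.clip((theta // 90.0).astype(int), 0, 3)
    frac = (theta - 90.0 * quad) / 90.0
    out = np.zeros(np.broadcast(x, y).shape, dtype=float)
    r_b = np.broadcast_to(r, out.shape)
    quad = np.broadcast_to(quad, out.shape)
    frac = np.broadcast_to(frac, out.shape)
    for q in range(4):
        mask = quad == q
        if not np.any(mask):
            continue
        m0 = _ANGLE_ORDER[q]
        m1 = _ANGLE_ORDER[(q + 1) % 4]
        v0 = mset(r_b[mask], m0)
        v1 = mset(r_b[mask], m1)
        out[mask] = (1.0 - frac[mask]) * v0 + frac[mask] * v1
    return out if out.ndim else float(out)


def build_density_map(
    meridians: MeridianDensitySet,
    region: tuple[float, float, float, float],
    resolution: float = 0.05,
) -> DensityMap:
    """Sample the polar-interpolated meridian model over a rectangular region.

    ``region`` is (x0, x1, y0, y1) in degrees; ``resolution`` is the grid step.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    x0, x1, y0, y1 = region
    if min(x0, y0) < -MAX_ECC_DEG or max(x1, y1) > MAX_ECC_DEG:
        raise ValueError(f"region must lie within [-{MAX_ECC_DEG}, {MAX_ECC_DEG}] deg")
    nx = max(2, int(round((x1 - x0) / resolution)) + 1)
    ny = max(2, int(round((y1 - y0) / resolution)) + 1)
    xs = np.linspace(x0, x1, nx)
    ys = np.linspace(y0, y1, ny)
    xx, yy = np.meshgrid(xs, ys)
    vals = _polar_density(meridians, xx, yy)
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("density map must be positive and finite everywhere")
    return DensityMap(xs, ys, vals, meridians.cell_class, meridians)
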