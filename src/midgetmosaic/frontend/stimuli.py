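"""Stimuli specified in cone-contrast terms on a calibrated display.

All stimuli are defined by a spatial pattern in [-1, 1] multiplying a
per-cone-class contrast triple (C_L, C_M, C_S), around a fixed background
(mean chromaticity (0.30, 0.32), 100 cd/m^2 by default). Drift is modeled
as static phase steps over one cycle (the response model is instantaneous).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorimetry import Display

__all__ = [
    "Stimulus",
    "make_drifting_grating",
    "make_white_noise_checkerboard",
    "make_uniform_field",
    "achromatic",
    "l_minus_m",
]


def achromatic(c: float) -> np.ndarray:
    """In-phase L=M=S cone contrast triple."""
    return np.array([c, c, c], dtype=float)


def l_minus_m(c: float) -> np.ndarray:
    """L and M in antiphase, S silent."""
    return np.array([c, -c, 0.0], dtype=float)


@dataclass
class Stimulus:
    kind: str  # drifting_grating | white_noise_checkerboard | uniform_field
    cone_contrast: np.ndarray  # (C_L, C_M, C_S)
    region: tuple[float, float, float, float]
    display: Display
    spatial_frequency: float = 0.0  # cyc/deg (gratings)
    orientation_deg: float = 0.0  # grating bar orientation; drift is normal to it
    n_phases: int = 16
    check_size_deg: float = 0.05
    n_frames: int = 0
    seed: int = 0
    noise_contrast: float = 0.5

    @property
    def n_t(self) -> int:
        return self.n_phases if self.kind == "drifting_grating" else max(self.n_frames, 1)

    @property
    def phases(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_phases) / self.n_phases

    def pattern(self, x, y, t: int):
        """Ideal (pre-optics) spatial pattern in [-1, 1] at frame t."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.kind == "uniform_field":
            return np.full(np.broadcast(x, y).shape, np.sin(self.phases[t % self.n_phases]))
        if self.kind == "drifting_grating":
            u = self._along(x, y)
            return np.sin(2.0 * np.pi * self.spatial_frequency * u + self.phases[t])
        if self.kind == "white_noise_checkerboard":
            vals = self.noise_values()
            ix, iy, inside = self._check_index(x, y)
            out = np.zeros(np.broadcast(x, y).shape)
            out[inside] = vals[t].reshape(self.check_grid_shape())[iy[inside], ix[inside]]
            return out
        raise ValueError(f"unknown stimulus kind {self.kind!r}")

    def contrast_frames(self, points: np.ndarray) -> np.ndarray:
        """Ideal cone-contrast frames at sample points: shape (3, n_points, n_t)."""
        pts = np.atleast_2d(points)
        out = np.empty((3, len(pts), self.n_t))
        for t in range(self.n_t):
            pat = self.pattern(pts[:, 0], pts[:, 1], t)
            out[:, :, t] = self.cone_contrast[:, None] * pat[None, :]
        return out

    # -- gratings -------------------------------------------------------
    def _along(self, x, y):
        """Coordinate along the drift direction (normal to the bars)."""
        th = np.radians(self.orientation_deg)
        return -x * np.sin(th) + y * np.cos(th)

    # -- white noise ----------------------------------------------------
    def check_grid_shape(self) -> tuple[int, int]:
        x0, x1, y0, y1 = self.region
        nx = max(1, int(np.ceil((x1 - x0) / self.check_size_deg)))
        ny = max(1, int(np.ceil((y1 - y0) / self.check_size_deg)))
        return ny, nx

    def check_centers(self) -> np.ndarray:
        x0, x1, y0, y1 = self.region
        ny, nx = self.check_grid_shape()
        cx = x0 + (np.arange(nx) + 0.5) * self.check_size_deg
        cy = y0 + (np.arange(ny) + 0.5) * self.check_size_deg
        xx, yy = np.meshgrid(cx, cy)
        return np.stack([xx.ravel(), yy.ravel()], axis=1)

    def _check_index(self, x, y):
        x0, x1, y0, y1 = self.region
        ny, nx = self.check_grid_shape()
        ix = np.floor((np.asarray(x) - x0) / self.check_size_deg).astype(int)
        iy = np.floor((np.asarray(y) - y0) / self.check_size_deg).astype(int)
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        return np.clip(ix, 0, nx - 1), np.clip(iy, 0, ny - 1), inside

    def noise_values(self) -> np.ndarray:
        """Binary +-1 check values, shape (n_frames, n_checks); reproducible from seed."""
        ny, nx = self.check_grid_shape()
        rng = np.random.default_rng(self.seed)
        return rng.choice([-1.0, 1.0], size=(self.n_frames, ny * nx))


def _validated(display, contrast):
    display = display if display is not None else Display()
    display.primary_weights_for_cone_contrast(contrast)  # gamut check
    return display


def make_drifting_grating(
    spatial_frequency: float,
    orientation_deg: float,
    cone_contrast,
    region,
    n_phases: int = 16,
    display: Display | None = None,
) -> Stimulus:
    """Drifting sinusoidal grating in cone-contrast units.

    ``cone_contrast`` is (C_L, C_M, C_S); use :func:`achromatic` or
    :func:`l_minus_m` for the standard specs. Drift is represented as
    ``n_phases`` static phase steps per cycle (>= 8).
    """
    if spatial_frequency < 0:
        raise ValueError("spatial frequency must be >= 0")
    if n_phases < 8:
        raise ValueError("need at least 8 phases per cycle")
    contrast = np.asarray(cone_contrast, dtype=float)
    display = _validated(display, contrast)
    return Stimulus("drifting_grating", contrast, tuple(region), display,
                    spatial_frequency=spatial_frequency, orientation_deg=orientation_deg,
                    n_phases=n_phases)


def make_white_noise_checkerboard(
    check_size_deg: float,
    n_frames: int,
    seed: int,
    region,
    contrast: float = 0.5,
    display: Display | None = None,
) -> Stimulus:
    """Binary achromatic white-noise checkerboard (i.i.d. +-contrast per check/frame)."""
    if check_size_deg <= 0:
        raise ValueError("check size must be positive")
    spec = achromatic(contrast)
    display = _validated(display, spec)
    return Stimulus("white_noise_checkerboard", spec, tuple(region), display,
                    check_size_deg=check_size_deg, n_frames=n_frames, seed=seed,
                    noise_contrast=contrast)


def make_uniform_field(
    cone_contrast,
    region,
    n_phases: int = 16,
    display: Display | None = None,
) -> Stimulus:
    """Spatially uniform field, sinusoidally modulated in time."""
    contrast = np.asarray(cone_contrast, dtype=float)
    display = _validated(display, contrast)
    return Stimulus("uniform_field", contrast, tuple(region), display, n_phases=n_phases)
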