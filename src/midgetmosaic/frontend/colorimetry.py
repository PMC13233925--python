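"""Colorimetry: CIE color matching, cone fundamentals, and the display model.

The CIE 1931 color matching functions are evaluated from the standard
piecewise-Gaussian analytic fits (Wyman, Sloan & Shirley 2013), and LMS cone
fundamentals are obtained from them through the Hunt-Pointer-Estevez
transform. Fundamentals are fixed across eccentricity (foveal 2-degree
values); eccentricity-varying inert pigments are a documented simplification.

The display is a three-primary monitor with smooth CRT-like primary spectra
and effectively continuous (20-bit) channel resolution. Stimuli specified in
cone contrast are converted to primary modulations by inverting the
primaries-by-fundamentals matrix at the background operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WAVELENGTHS_NM", "xyz_cmfs", "cone_fundamentals", "Display"]

# 400-700 nm at 10 nm: enough spectral resolution for smooth primaries and LCA
WAVELENGTHS_NM = np.arange(400.0, 701.0, 10.0)


def _pw_gauss(lam, alpha, mu, sig_l, sig_r):
    sig = np.where(lam < mu, sig_l, sig_r)
    return alpha * np.exp(-0.5 * ((lam - mu) / sig) ** 2)


def xyz_cmfs(lam=WAVELENGTHS_NM):
    """CIE 1931 xbar, ybar, zbar via multi-lobe piecewise-Gaussian fits."""
    lam = np.asarray(lam, dtype=float)
    x = (
        _pw_gauss(lam, 1.056, 599.8, 37.9, 31.0)
        + _pw_gauss(lam, 0.362, 442.0, 16.0, 26.7)
        + _pw_gauss(lam, -0.065, 501.1, 20.4, 26.2)
    )
    y = _pw_gauss(lam, 0.821, 568.8, 46.9, 40.5) + _pw_gauss(lam, 0.286, 530.9, 16.3, 31.1)
    z = _pw_gauss(lam, 1.217, 437.0, 11.8, 36.0) + _pw_gauss(lam, 0.681, 459.0, 26.0, 13.8)
    return np.clip(np.stack([x, y, z]), 0.0, None)


# Hunt-Pointer-Estevez XYZ -> LMS (D65-normalized variant)
_HPE = np.array(
    [
        [0.38971, 0.68898, -0.07868],
        [-0.22981, 1.18340, 0.04641],
        [0.00000, 0.00000, 1.00000],
    ]
)


def cone_fundamentals(lam=WAVELENGTHS_NM):
    """L, M, S spectral sensitivities, shape (3, n_wavelengths), peak-normalized."""
    lms = np.clip(_HPE @ xyz_cmfs(lam), 0.0, None)
    return lms / lms.max(axis=1, keepdims=True)


def _gauss(lam, mu, sig):
    return np.exp(-0.5 * ((lam - mu) / sig) ** 2)


@dataclass
class Display:
    """Three-primary display at a fixed background chromaticity and luminance.

    The background defaults to (x, y) = (0.30, 0.32) at 100 cd/m^2. All
    radiance bookkeeping is relative (the absolute scale cancels in cone
    contrast); luminance fixes the scale via the CIE ybar integral.
    """

    mean_chromaticity: tuple[float, float] = (0.30, 0.32)
    mean_luminance: float = 100.0
    lam: np.ndarray = field(default_factory=lambda: WAVELENGTHS_NM.copy())

    def __post_init__(self):
        lam = self.lam
        # smooth CRT-like primaries
        self.primaries = np.stack(
            [_gauss(lam, 610.0, 25.0), _gauss(lam, 545.0, 25.0), _gauss(lam, 450.0, 20.0)]
        )
        xyz = xyz_cmfs(lam)
        self._xyz_of_primary = xyz @ self.primaries.T * (lam[1] - lam[0])  # (3 XYZ, 3 prim)
        x, y = self.mean_chromaticity
        Y = self.mean_luminance
        target = np.array([x / y * Y, Y, (1 - x - y) / y * Y])
        self.bg_weights = np.linalg.solve(self._xyz_of_primary, target)
        if np.any(self.bg_weights <= 0):
            raise ValueError("background chromaticity outside display gamut")
        self.fundamentals = cone_fundamentals(lam)
        # cone excitation produced by unit weight of each primary: (3 cones, 3 prim)
        self._lms_of_primary = self.fundamentals @ self.primaries.T * (lam[1] - lam[0])
        self.bg_excitations = self._lms_of_primary @ self.bg_weights
        self.bg_radiance = self.primaries.T @ self.bg_weights  # per wavelength

    def primary_weights_for_cone_contrast(self, contrast: np.ndarray) -> np.ndarray:
        """Primary-weight modulation producing the given (C_L, C_M, C_S) at unit pattern.

        Raises a gamut error if the modulation would drive any primary
        negative (or past twice its background weight) at full swing.
        """
        contrast = np.asarray(contrast, dtype=float)
        d_lms = self.bg_excitations * contrast
        dw = np.linalg.solve(self._lms_of_primary, d_lms)
        if np.any(np.abs(dw) > self.bg_weights):
            raise ValueError(
                "cone-contrast spec outside display gamut at this background"
            )
        return dw

    def radiance_modulation(self, contrast: np.ndarray) -> np.ndarray:
        """Spectral radiance modulation (per wavelength) for a unit contrast pattern."""
        return self.primaries.T @ self.primary_weights_for_cone_contrast(contrast)
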