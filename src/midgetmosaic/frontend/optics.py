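"""Simplified physiological optics.

The optical transfer function is the product of three real factors:

* diffraction by a circular pupil (Airy MTF, wavelength dependent),
* defocus, combining a reduced-eye longitudinal chromatic aberration (LCA)
  term with any residual defocus, applied as the geometrical thin-lens
  transfer 2*J1(pi*beta*f)/(pi*beta*f) for a blur disk of angular diameter
  beta = defocus(D) * pupil(m) radians (this factor is signed: spatial
  frequencies beyond its first zero are phase reversed, which is what lets
  LCA reverse the retinal phase of chromatic grating components),
* an elongated Gaussian blur whose sigmas grow with eccentricity and whose
  major axis is radial, standing in for the aberrations of peripheral optics.

``diffraction_limited`` mode keeps only the Airy factor and disables LCA.
Every monochromatic PSF integrates to one (OTF(0) = 1), so uniform scenes
are fixed points of the optics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import j1

__all__ = ["OpticsModel", "lca_defocus_diopters", "optimize_defocus_strehl"]


def lca_defocus_diopters(lam_nm, in_focus_nm: float = 550.0):
    """Reduced-eye chromatic defocus (diopters) relative to the in-focus wavelength."""

    def rx(l_um):
        return 1.68524 - 0.63346 / (l_um - 0.21410)

    return rx(np.asarray(lam_nm, dtype=float) / 1e3) - rx(in_focus_nm / 1e3)


def _airy_mtf(f_cpd, lam_nm, pupil_mm):
    fc = (pupil_mm * 1e-3) / (lam_nm * 1e-9) * np.pi / 180.0  # cutoff, cyc/deg
    nu = np.clip(np.abs(f_cpd) / fc, 0.0, 1.0)
    return (2.0 / np.pi) * (np.arccos(nu) - nu * np.sqrt(1.0 - nu**2))


def _jinc(x):
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-9
    out[nz] = 2.0 * j1(np.pi * x[nz]) / (np.pi * x[nz])
    return out


@dataclass
class OpticsModel:
    """Pluggable optics for one retinal location.

    Parameters
    ----------
    mode : {"diffraction_limited", "simplified_physiological"}
    pupil_mm : pupil diameter.
    in_focus_nm : wavelength of best focus (LCA zero).
    eccentricity_deg : (x, y) of the modeled patch center; sets the
        orientation (radial) and magnitude of the Gaussian blur.
    defocus_offset : intrinsic refractive error (diopters).
    residual_defocus : corrective defocus added on top (diopters); set by
        :func:`optimize_defocus_strehl`.
    """

    mode: str = "simplified_physiological"
    pupil_mm: float = 3.0
    in_focus_nm: float = 550.0
    eccentricity_deg: tuple[float, float] = (0.0, 0.0)
    defocus_offset: float = 0.0
    residual_defocus: float = 0.0
    blur_base_deg: float = 0.004
    blur_minor_slope: float = 0.0010
    blur_major_slope: float = 0.0025

    def __post_init__(self):
        if self.mode not in ("diffraction_limited", "simplified_physiological"):
            raise ValueError(f"unknown optics mode {self.mode!r}")

    # -- geometry -------------------------------------------------------
    @property
    def ecc_radius(self) -> float:
        return float(np.hypot(*self.eccentricity_deg))

    @property
    def elongation_axis_deg(self) -> float:
        """Orientation of the blur major axis (radial from the fovea)."""
        x, y = self.eccentricity_deg
        if x == 0 and y == 0:
            return 0.0
        return float(np.degrees(np.arctan2(y, x)))

    def blur_sigmas(self) -> tuple[float, float]:
        if self.mode == "diffraction_limited":
            return 0.0, 0.0
        e = self.ecc_radius
        return (
            self.blur_base_deg + self.blur_major_slope * e,
            self.blur_base_deg + self.blur_minor_slope * e,
        )

    def defocus_at(self, lam_nm):
        if self.mode == "diffraction_limited":
            return np.zeros_like(np.asarray(lam_nm, dtype=float))
        return (
            lca_defocus_diopters(lam_nm, self.in_focus_nm)
            + self.defocus_offset
            + self.residual_defocus
        )

    # -- transfer functions ---------------------------------------------
    def otf(self, fx_cpd, fy_cpd, lam_nm: float):
        """Signed OTF at 2D frequency (cyc/deg) for one wavelength."""
        fx = np.asarray(fx_cpd, dtype=float)
        fy = np.asarray(fy_cpd, dtype=float)
        f = np.hypot(fx, fy)
        out = _airy_mtf(f, lam_nm, self.pupil_mm)
        dd = float(np.asarray(self.defocus_at(lam_nm)))
        if dd != 0.0:
            beta_deg = abs(dd) * self.pupil_mm * 1e-3 * 180.0 / np.pi
            out = out * _jinc(beta_deg * f)
        sig_maj, sig_min = self.blur_sigmas()
        if sig_maj > 0:
            th = np.radians(self.elongation_axis_deg)
            fu = fx * np.cos(th) + fy * np.sin(th)
            fv = -fx * np.sin(th) + fy * np.cos(th)
            out = out * np.exp(-2.0 * np.pi**2 * (sig_maj**2 * fu**2 + sig_min**2 * fv**2))
        return out

    def gaussian_equivalent_sigma(self, lam_nm: float) -> float:
        """Sigma (deg) of the Gaussian whose MTF matches this OTF at half power.

        Used to approximate the PSF when blurring non-sinusoidal stimuli
        (white-noise checks) where the exact OTF shape is secondary.
        """
        f = np.linspace(0.0, 120.0, 2401)[1:]
        m = self.otf(f, 0.0, lam_nm)
        below = np.nonzero(m <= 0.5)[0]
        if len(below) == 0:
            return 0.0
        i = below[0]
        f50 = np.interp(0.5, [m[i], m[i - 1]], [f[i], f[i - 1]]) if i > 0 else f[i]
        return float(np.sqrt(np.log(2.0) / 2.0) / (np.pi * f50))

    def psf_kernel(self, lam_nm: float, extent_deg: float = 0.2, n: int = 129):
        """Spatial PSF on a square pixel grid (normalized to sum 1)."""
        dx = extent_deg / n
        f = np.fft.fftfreq(n, d=dx)
        fx, fy = np.meshgrid(f, f)
        otf = self.otf(fx, fy, lam_nm)
        psf = np.real(np.fft.ifft2(otf))
        psf = np.fft.fftshift(psf)
        s = psf.sum()
        if s <= 0:
            raise ValueError("degenerate PSF")
        return psf / s

    def strehl_ratio(self, lam_nm: float | None = None) -> float:
        """Peak PSF sensitivity relative to the diffraction-limited PSF."""
        lam = self.in_focus_nm if lam_nm is None else lam_nm
        f = np.linspace(-130.0, 130.0, 321)
        fx, fy = np.meshgrid(f, f)
        num = np.trapezoid(np.trapezoid(self.otf(fx, fy, lam), f, axis=1), f, axis=0)
        ref = OpticsModel("diffraction_limited", pupil_mm=self.pupil_mm,
                          in_focus_nm=self.in_focus_nm)
        den = np.trapezoid(np.trapezoid(ref.otf(fx, fy, lam), f, axis=1), f, axis=0)
        return float(num / den)


def optimize_defocus_strehl(optics: OpticsModel, bracket: float = 3.0) -> float:
    """Residual defocus (diopters) maximizing the Strehl ratio at the focus wavelength.

    A coarse 0.1-diopter grid brackets the optimum, followed by a bounded
    scalar refinement; falls back to the best grid node (with a warning) if
    the optimum sits at the bracket edge.
    """
    from scipy.optimize import minimize_scalar

    if optics.mode == "diffraction_limited":
        return 0.0

    def neg_strehl(res):
        trial = OpticsModel(
            optics.mode, optics.pupil_mm, optics.in_focus_nm, optics.eccentricity_deg,
            optics.defocus_offset, float(res),
            optics.blur_base_deg, optics.blur_minor_slope, optics.blur_major_slope,
        )
        return -trial.strehl_ratio()

    grid = np.arange(-bracket, bracket + 1e-9, 0.1)
    vals = np.array([neg_strehl(g) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if i in (0, len(grid) - 1):
        import warnings

        warnings.warn("Strehl optimum at bracket edge; returning grid best",
                      RuntimeWarning, stacklevel=2)
        return float(grid[i])
    res = minimize_scalar(neg_strehl, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)
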