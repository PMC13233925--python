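"""Cone excitations: stimulus -> optics -> aperture sampling -> contrast.

Gratings (and uniform fields, their zero-frequency limit) are propagated
analytically: a sinusoid passes through the optics as the same sinusoid
scaled by the signed OTF at each wavelength, so each cone class's retinal
contrast amplitude is a wavelength sum of OTF-weighted spectral modulation,
further attenuated by the Gaussian cone aperture MTF. White-noise
checkerboards use a cone-by-check coupling matrix built from the Gaussian
equivalent of the PSF convolved with the cone aperture. Both paths are
checked against brute-force pixel convolution in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.special import erf

from ..lattice import ConeMosaic
from .optics import OpticsModel
from .stimuli import Stimulus

__all__ = ["ConeExcitationFrame", "compute_cone_excitations", "cone_contrast"]


@dataclass
class ConeExcitationFrame:
    """Per-cone excitations for a stimulus and its adapting background."""

    E_stim: np.ndarray  # (n_cones, n_t)
    E_bkgnd: np.ndarray  # (n_cones,)

    @property
    def C_stim(self) -> np.ndarray:
        return cone_contrast(self.E_stim, self.E_bkgnd)


def cone_contrast(E_stim, E_bkgnd):
    """(E_stim - E_bkgnd) / E_bkgnd, elementwise over cones and frames."""
    E_stim = np.asarray(E_stim, dtype=float)
    E_bkgnd = np.asarray(E_bkgnd, dtype=float)
    if np.any(E_bkgnd <= 0):
        bad = int(np.argmax(E_bkgnd <= 0))
        raise ZeroDivisionError(f"zero background excitation for cone {bad}")
    return (E_stim - E_bkgnd[:, None] if E_stim.ndim == 2 else E_stim - E_bkgnd) / (
        E_bkgnd[:, None] if E_stim.ndim == 2 else E_bkgnd
    )


def _spectral_terms(stimulus: Stimulus):
    disp = stimulus.display
    dlam = disp.lam[1] - disp.lam[0]
    bg = disp.fundamentals @ disp.bg_radiance * dlam  # (3,) background excitation rates
    d_i = disp.radiance_modulation(stimulus.cone_contrast)  # per wavelength
    return disp, bg, d_i, dlam


def _grating_class_amplitudes(stimulus: Stimulus, optics: OpticsModel):
    """Signed retinal contrast amplitude per cone class (before aperture MTF)."""
    disp, bg, d_i, dlam = _spectral_terms(stimulus)
    th = np.radians(stimulus.orientation_deg)
    w = stimulus.spatial_frequency
    fx, fy = -w * np.sin(th), w * np.cos(th)
    otf = np.array([optics.otf(fx, fy, lam) for lam in disp.lam])
    amp = (disp.fundamentals * (d_i * otf)[None, :]).sum(axis=1) * dlam
    return amp / bg, bg


def _background_excitations(mosaic: ConeMosaic, bg_rates: np.ndarray) -> np.ndarray:
    area = 2.0 * np.pi * mosaic.aperture_sigma**2  # Gaussian collecting area
    return bg_rates[mosaic.types] * area


def _check_coupling(stimulus: Stimulus, optics: OpticsModel, mosaic: ConeMosaic):
    """Sparse cone-by-check sensitivity matrix (rows sum to ~1 in the interior)."""
    from scipy.spatial import cKDTree

    disp, bg, d_i, dlam = _spectral_terms(stimulus)
    w = disp.fundamentals * d_i[None, :]  # spectral weight per class
    sig_psf = np.array([optics.gaussian_equivalent_sigma(lam) for lam in disp.lam])
    cls_sig = (np.abs(w) @ sig_psf) / np.abs(w).sum(axis=1)
    sig_eff = np.sqrt(mosaic.aperture_sigma**2 + cls_sig[mosaic.types] ** 2)
    centers = stimulus.check_centers()
    h = stimulus.check_size_deg
    tree = cKDTree(centers)
    pts = mosaic.positions
    rows, cols, vals = [], [], []
    for i in range(len(pts)):
        rad = 4.0 * sig_eff[i] + h
        idx = tree.query_ball_point(pts[i], r=rad)
        if not idx:
            continue
        c = centers[idx]
        s = sig_eff[i] * np.sqrt(2.0)
        gx = 0.5 * (erf((c[:, 0] + h / 2 - pts[i, 0]) / s) - erf((c[:, 0] - h / 2 - pts[i, 0]) / s))
        gy = 0.5 * (erf((c[:, 1] + h / 2 - pts[i, 1]) / s) - erf((c[:, 1] - h / 2 - pts[i, 1]) / s))
        v = gx * gy
        rows.extend([i] * len(idx))
        cols.extend(idx)
        vals.extend(v)
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(len(pts), len(centers)))
    return A, bg


def compute_cone_excitations(
    stimulus: Stimulus, optics: OpticsModel, mosaic: ConeMosaic
) -> ConeExcitationFrame:
    """Excitation of every cone on every frame, plus the adapting background.

    The background is the cone's response to a uniform field with the
    stimulus's mean chromaticity and luminance, so ``C_stim`` is zero
    wherever the stimulus equals the background.
    """
    x0, x1, y0, y1 = stimulus.region
    p = mosaic.positions
    if (p[:, 0].min() < x0 or p[:, 0].max() > x1
            or p[:, 1].min() < y0 or p[:, 1].max() > y1):
        raise ValueError("cone mosaic extends outside the stimulus region")
    if stimulus.kind in ("drifting_grating", "uniform_field"):
        amp, bg = _grating_class_amplitudes(stimulus, optics)
        w = stimulus.spatial_frequency
        ap = np.exp(-2.0 * np.pi**2 * mosaic.aperture_sigma**2 * w**2)
        a_i = amp[mosaic.types] * ap
        if stimulus.kind == "uniform_field":
            phase_t = np.sin(stimulus.phases)
            C = a_i[:, None] * phase_t[None, :]
        else:
            th = np.radians(stimulus.orientation_deg)
            u = -p[:, 0] * np.sin(th) + p[:, 1] * np.cos(th)
            arg = 2.0 * np.pi * w * u
            C = a_i[:, None] * np.sin(arg[:, None] + stimulus.phases[None, :])
    elif stimulus.kind == "white_noise_checkerboard":
        A, bg = _check_coupling(stimulus, optics, mosaic)
        noise = stimulus.noise_values()  # (n_frames, n_checks)
        C = stimulus.noise_contrast * (A @ noise.T)
    else:
        raise ValueError(f"unknown stimulus kind {stimulus.kind!r}")
    E_b = _background_excitations(mosaic, bg)
    E = E_b[:, None] * (1.0 + C)
    return ConeExcitationFrame(E, E_b)
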