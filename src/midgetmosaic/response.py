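"""Linear mRGC responses and simulated physiology probes.

The response of cell k to a cone-contrast frame C(:, t) is

    R(k, t) = [ sum_i Pc(i,k) C(i,t) - sum_j Ps(j,k) C(j,t) ] / sum_i Pc(i,k)

i.e. an instantaneous center-minus-surround weighted sum normalized by the
integrated center weight. Two probes reproduce standard physiology: spatial
transfer functions measured with drifting gratings (amplitude of the fitted
sinusoid at the drift frequency per spatial frequency), and receptive-field
maps recovered by cross-correlating responses with a white-noise stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .frontend.excitations import compute_cone_excitations
from .frontend.optics import OpticsModel
from .frontend.stimuli import achromatic, make_drifting_grating, make_white_noise_checkerboard

__all__ = [
    "MosaicResponse",
    "compute_responses",
    "sinusoid_amplitude",
    "measure_vstf",
    "map_rf_white_noise",
    "RFMap",
    "RFEllipse",
    "fit_ellipsoid",
]


@dataclass
class MosaicResponse:
    R_stim: np.ndarray  # (n_cells, n_t)
    R_center: np.ndarray
    R_surround: np.ndarray


def compute_responses(C_stim, P_center, P_surround=None) -> MosaicResponse:
    """Exact center-minus-surround arithmetic; linear in the contrast input."""
    C = np.atleast_2d(np.asarray(C_stim, dtype=float))
    Pc = sparse.csr_matrix(P_center)
    norm = np.asarray(Pc.sum(axis=0)).ravel()
    if np.any(norm <= 0):
        bad = int(np.argmax(norm <= 0))
        raise ZeroDivisionError(f"cell {bad} has zero integrated center weight")
    Rc = (Pc.T @ C) / norm[:, None]
    if P_surround is not None:
        Ps = sparse.csr_matrix(P_surround)
        Rs = (Ps.T @ C) / norm[:, None]
    else:
        Rs = np.zeros_like(Rc)
    return MosaicResponse(Rc - Rs, Rc, Rs)


def sinusoid_amplitude(R: np.ndarray) -> np.ndarray:
    """Least-squares sinusoid amplitude at one cycle per record.

    For uniformly spaced phases this equals twice the magnitude of the
    fundamental DFT bin over the record length.
    """
    R = np.atleast_2d(R)
    n = R.shape[-1]
    return 2.0 * np.abs(np.fft.rfft(R, axis=-1)[..., 1]) / n


def measure_vstf(
    cone_mosaic,
    P_center,
    P_surround,
    optics: OpticsModel,
    sf_list,
    orientation_deg: float = 0.0,
    contrast: float = 0.5,
    n_phases: int = 16,
    cell_ids=None,
    region=None,
):
    """Spatial transfer functions by probing with drifting achromatic gratings.

    Returns an array (n_cells_or_selected, n_sf) of response amplitudes.
    ``orientation_deg`` is the grating bar orientation (fixed policy); pass
    the per-cell matched orientation externally for the matched policy.
    """
    pts = cone_mosaic.positions
    if region is None:
        pad = 1e-6
        region = (pts[:, 0].min() - pad, pts[:, 0].max() + pad,
                  pts[:, 1].min() - pad, pts[:, 1].max() + pad)
    out = []
    for w in sf_list:
        stim = make_drifting_grating(w, orientation_deg, achromatic(contrast),
                                     region, n_phases=n_phases)
        C = compute_cone_excitations(stim, optics, cone_mosaic).C_stim
        R = compute_responses(C, P_center, P_surround).R_stim
        out.append(sinusoid_amplitude(R))
    amp = np.stack(out, axis=1)
    return amp if cell_ids is None else amp[np.asarray(cell_ids)]


@dataclass
class RFMap:
    """Signed spatial sensitivity map on the white-noise check grid."""

    values: np.ndarray  # (ny, nx); increment-excitatory positive
    x_deg: np.ndarray
    y_deg: np.ndarray
    source: str  # retinal_space | visual_space
    noise_floor: float = 0.0


def map_rf_white_noise(
    cone_mosaic,
    P_center,
    P_surround,
    optics: OpticsModel,
    cell_ids,
    region,
    check_size_deg: float,
    n_frames: int = 4000,
    seed: int = 0,
    contrast: float = 0.5,
) -> list[RFMap]:
    """Receptive-field maps by reverse correlation with binary white noise.

    map(x) = sum_t contrast(x, t) R(k, t) / n_frames. The noise floor is
    estimated from a temporally shuffled control (seeded).
    """
    stim = make_white_noise_checkerboard(check_size_deg, n_frames, seed, region,
                                         contrast=contrast)
    C = compute_cone_excitations(stim, optics, cone_mosaic).C_stim
    R = compute_responses(C, P_center, P_surround).R_stim
    noise = stim.noise_values()  # (n_frames, n_checks)
    ny, nx = stim.check_grid_shape()
    centers = stim.check_centers()
    xs = np.unique(centers[:, 0])
    ys = np.unique(centers[:, 1])
    rng = np.random.default_rng(seed + 1)
    src = "retinal_space" if optics.mode == "diffraction_limited" else "visual_space"
    maps = []
    for k in np.atleast_1d(cell_ids):
        m = (noise.T @ R[k]) / n_frames
        perm = rng.permutation(n_frames)
        floor = float(np.std((noise.T @ R[k][perm]) / n_frames))
        maps.append(RFMap(m.reshape(ny, nx), xs, ys, src, floor))
    return maps


@dataclass
class RFEllipse:
    center: tuple[float, float]
    sigma_minor: float
    sigma_major: float
    orientation_deg: float

    @property
    def diameter(self) -> float:
        """RF diameter: 2 * sqrt(sigma_minor * sigma_major)."""
        return 2.0 * np.sqrt(self.sigma_minor * self.sigma_major)


def fit_ellipsoid(rf_map: RFMap) -> RFEllipse:
    """2D Gaussian fit to the increment-excitatory (positive) part of a map."""
    from scipy.optimize import least_squares

    v = np.clip(rf_map.values, 0.0, None)
    if v.max() <= 0:
        raise ValueError("map has no positive lobe to fit")
    xx, yy = np.meshgrid(rf_map.x_deg, rf_map.y_deg)
    w = v / v.sum()
    mx, my = float((w * xx).sum()), float((w * yy).sum())
    cxx = float((w * (xx - mx) ** 2).sum())
    cyy = float((w * (yy - my) ** 2).sum())
    cxy = float((w * (xx - mx) * (yy - my)).sum())

    def model(p):
        a, x0, y0, lsx, lsy, th = p
        sx, sy = np.exp(lsx), np.exp(lsy)
        u = (xx - x0) * np.cos(th) + (yy - y0) * np.sin(th)
        vv = -(xx - x0) * np.sin(th) + (yy - y0) * np.cos(th)
        return a * np.exp(-0.5 * ((u / sx) ** 2 + (vv / sy) ** 2))

    theta0 = 0.5 * np.arctan2(2 * cxy, cxx - cyy) if cxx != cyy or cxy else 0.0
    p0 = np.array([v.max(), mx, my,
                   0.5 * np.log(max(cxx, 1e-12)), 0.5 * np.log(max(cyy, 1e-12)), theta0])
    res = least_squares(lambda p: (model(p) - v).ravel(), p0, method="lm",
                        max_nfev=4000)
    a, x0, y0, lsx, lsy, th = res.x
    sx, sy = np.exp(lsx), np.exp(lsy)
    if sx >= sy:
        s_maj, s_min, ang = sx, sy, np.degrees(th)
    else:
        s_maj, s_min, ang = sy, sx, np.degrees(th) + 90.0
    ang = (ang + 90.0) % 180.0 - 90.0
    return RFEllipse((float(x0), float(y0)), float(s_min), float(s_maj), float(ang))
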