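"""Template-matching computational observer on noisy mosaic responses.

Responses (cone contrasts or mRGC responses, over space and drift phase)
are corrupted by i.i.d. zero-mean Gaussian noise. A two-interval trial
presents the test stimulus and a zero-contrast stimulus; the observer
correlates each noisy response vector with the noise-free template
difference and picks the interval with the larger inner product. Threshold
is the contrast at which a cumulative-Gaussian psychometric function fitted
in log contrast crosses the criterion (80.6% correct by default), and
contrast sensitivity is its reciprocal. Because the noise level is a free
scalar, predicted sensitivities are meaningful in relative terms only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import ndtr, ndtri

from .frontend.excitations import compute_cone_excitations
from .frontend.optics import OpticsModel
from .frontend.stimuli import achromatic, l_minus_m, make_drifting_grating, make_uniform_field
from .response import compute_responses

__all__ = [
    "ObserverConfig",
    "simulate_trials",
    "find_threshold",
    "CSF",
    "compute_csf",
    "ThresholdContour",
    "chromatic_threshold_contour",
]


@dataclass
class ObserverConfig:
    noise_sigma: float = 0.05
    criterion: float = 0.806
    n_trials: int = 256
    n_levels: int = 7
    representation: str = "mrgc"  # or "cone_excitations"
    seed: int = 0

    def __post_init__(self):
        if not 0.5 < self.criterion < 1.0:
            raise ValueError("criterion must lie in (0.5, 1)")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")


def simulate_trials(template_test, template_null, config: ObserverConfig,
                    rng, n_trials: int | None = None) -> np.ndarray:
    """Boolean per-trial outcomes of the two-interval template-matching rule."""
    t1 = np.asarray(template_test, dtype=float).ravel()
    t0 = np.asarray(template_null, dtype=float).ravel()
    n = config.n_trials if n_trials is None else n_trials
    delta = t1 - t0
    x1 = t1 + rng.normal(0.0, config.noise_sigma, (n, len(t1)))
    x0 = t0 + rng.normal(0.0, config.noise_sigma, (n, len(t0)))
    score = (x1 - x0) @ delta
    ties = score == 0
    if np.any(ties):
        score[ties] = rng.choice([-1.0, 1.0], size=int(ties.sum()))
    return score > 0


def expected_proportion_correct(template_test, template_null,
                                config: ObserverConfig) -> float:
    """Closed-form matched-filter performance Phi(||delta|| / (sigma sqrt(2)))."""
    delta = np.asarray(template_test, float).ravel() - np.asarray(template_null, float).ravel()
    return float(ndtr(np.linalg.norm(delta) / (config.noise_sigma * np.sqrt(2.0))))


def _psychometric_threshold(levels, pc, criterion):
    """Criterion crossing of a cumulative Gaussian fitted in log contrast."""
    lx = np.log(levels)

    def model(p):
        mu, sig = p
        return 0.5 + 0.5 * ndtr((lx - mu) / np.exp(sig))

    i0 = int(np.argmin(np.abs(pc - 0.75)))
    fit = least_squares(lambda p: model(p) - pc, [lx[i0], np.log(0.5)],
                        max_nfev=2000)
    mu, lsig = fit.x
    return float(np.exp(mu + np.exp(lsig) * ndtri(2.0 * criterion - 1.0))), mu, lsig


def find_threshold(template_fn, config: ObserverConfig,
                   contrast_max: float, contrast_min: float | None = None):
    """Contrast where the fitted psychometric function crosses the criterion.

    ``template_fn(contrast)`` returns the noise-free response template of the
    test stimulus at that contrast (the null template is its value at 0).
    A coarse log-spaced sweep brackets the criterion, then a second pass
    concentrates the levels around the first estimate (the log-contrast
    cumulative-Gaussian model is only locally exact). Raises a bracketing
    error when the criterion lies outside the measured performance range.
    """
    if contrast_min is None:
        contrast_min = contrast_max / 300.0
    t0 = np.asarray(template_fn(0.0), dtype=float).ravel()
    rng = np.random.default_rng(config.seed)

    def sweep(levels):
        pc = np.empty(len(levels))
        for i, c in enumerate(levels):
            t1 = np.asarray(template_fn(c), dtype=float).ravel()
            pc[i] = float(np.mean(simulate_trials(t1, t0, config, rng)))
        return pc

    levels = np.geomspace(contrast_min, contrast_max, config.n_levels)
    pc = sweep(levels)
    if not (pc.min() < config.criterion < pc.max()):
        raise ValueError(
            f"criterion {config.criterion} not bracketed; achieved "
            f"proportion-correct range [{pc.min():.3f}, {pc.max():.3f}] "
            f"over contrasts [{contrast_min:.2e}, {contrast_max:.2e}]")
    coarse, _, _ = _psychometric_threshold(levels, pc, config.criterion)
    levels2 = np.geomspace(max(coarse / 1.6, contrast_min),
                           min(1.6 * coarse, contrast_max), config.n_levels)
    pc2 = sweep(levels2)
    if pc2.min() < config.criterion < pc2.max():
        thr, mu, lsig = _psychometric_threshold(levels2, pc2, config.criterion)
        levels, pc = levels2, pc2
    else:
        thr, mu, lsig = _psychometric_threshold(levels, pc, config.criterion)
    return thr, {"levels": levels, "pc": pc, "mu": mu, "sigma": np.exp(lsig)}


# ---------------------------------------------------------------------------


@dataclass
class CSF:
    spatial_frequencies: np.ndarray
    sensitivity: np.ndarray  # 1 / threshold contrast
    chromatic_direction: str  # achromatic | L_minus_M
    representation: str
    thresholds: np.ndarray = field(default=None)


def _direction_spec(direction: str):
    if direction == "achromatic":
        return achromatic, 0.85
    if direction == "L_minus_M":
        return l_minus_m, 0.08
    raise ValueError(f"unknown chromatic direction {direction!r}")


def _stimulus_region(mosaic):
    p = mosaic.cone_mosaic.positions
    pad = 1e-6
    return (p[:, 0].min() - pad, p[:, 0].max() + pad,
            p[:, 1].min() - pad, p[:, 1].max() + pad)


def _template(mosaic, optics, stim, representation):
    C = compute_cone_excitations(stim, optics, mosaic.cone_mosaic).C_stim
    if representation == "cone_excitations":
        return C
    return compute_responses(C, mosaic.P_center, mosaic.P_surround).R_stim


def compute_csf(mosaic, optics: OpticsModel, sf_list, direction: str,
                config: ObserverConfig, orientation_deg: float | None = None,
                n_phases: int = 8) -> CSF:
    """Spatial contrast sensitivity of a mosaic for one chromatic direction.

    Gratings are oriented along the elongation axis of the optical PSF
    unless an orientation is given. Responses are linear in contrast, so the
    unit-contrast template is computed once per frequency and scaled.
    """
    spec_fn, c_max = _direction_spec(direction)
    region = _stimulus_region(mosaic)
    if orientation_deg is None:
        orientation_deg = optics.elongation_axis_deg
    thr = np.empty(len(sf_list))
    for i, w in enumerate(sf_list):
        c_ref = 0.5 * c_max
        stim = make_drifting_grating(w, orientation_deg, spec_fn(c_ref),
                                     region, n_phases=max(n_phases, 8))
        t_ref = _template(mosaic, optics, stim, config.representation)

        def template_fn(c):
            return (c / c_ref) * t_ref

        thr[i], _ = find_threshold(template_fn, config, contrast_max=c_max)
    return CSF(np.asarray(sf_list, float), 1.0 / thr, direction,
               config.representation, thr)


@dataclass
class ThresholdContour:
    theta_deg: np.ndarray
    thresholds: np.ndarray  # normalized: M-direction (90 deg) threshold = 1
    raw_thresholds: np.ndarray
    axis_ratio: float
    major_axis_deg: float


def chromatic_threshold_contour(mosaic, optics: OpticsModel, theta_list,
                                config: ObserverConfig,
                                rho_max: float = 0.08) -> ThresholdContour:
    """Detection-threshold contour in the L/M cone-contrast plane.

    Uniform fields modulated in time; per direction theta the contrast
    magnitude rho is varied, thresholds are normalized to the M direction
    (90 deg), and an ellipse is fitted to the threshold locus.
    """
    theta = np.asarray(theta_list, dtype=float)
    if not np.any(np.isclose(theta % 360, 90.0)):
        theta = np.append(theta, 90.0)
    region = _stimulus_region(mosaic)
    raw = np.empty(len(theta))
    for i, th in enumerate(theta):
        u = np.array([np.cos(np.radians(th)), np.sin(np.radians(th)), 0.0])
        c_ref = rho_max * 0.5
        stim = make_uniform_field(u * c_ref, region)
        t_ref = _template(mosaic, optics, stim, config.representation)

        def template_fn(c):
            return (c / c_ref) * t_ref

        raw[i], _ = find_threshold(template_fn, config, contrast_max=rho_max)
    m_thr = raw[np.isclose(theta % 360, 90.0)][0]
    norm = raw / m_thr
    pts = np.stack([norm * np.cos(np.radians(theta)),
                    norm * np.sin(np.radians(theta))], axis=1)
    ratio, major = _fit_ellipse(pts)
    return ThresholdContour(theta, norm, raw, ratio, major)


def _fit_ellipse(pts):
    """Axis ratio and major-axis angle of x'Ax = 1 fitted by linear LS."""
    x, y = pts[:, 0], pts[:, 1]
    M = np.stack([x**2, 2 * x * y, y**2], axis=1)
    coef, *_ = np.linalg.lstsq(M, np.ones(len(pts)), rcond=None)
    A = np.array([[coef[0], coef[1]], [coef[1], coef[2]]])
    evals, evecs = np.linalg.eigh(A)
    if np.any(evals <= 0):  # degenerate: report circle
        return 1.0, 0.0
    radii = 1.0 / np.sqrt(evals)  # descending radius = ascending eigenvalue
    if np.isclose(radii[0], radii[1]):
        return 1.0, 0.0
    major_vec = evecs[:, 0]  # smallest eigenvalue -> largest radius
    ang = np.degrees(np.arctan2(major_vec[1], major_vec[0])) % 180.0
    return float(radii[0] / radii[1]), float(ang)
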