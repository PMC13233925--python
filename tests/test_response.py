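"""Linear response engine, transfer-function and white-noise RF probes."""

import numpy as np
import pytest
from scipy import sparse

from midgetmosaic.frontend.optics import OpticsModel
from midgetmosaic.response import (
    RFMap,
    compute_responses,
    fit_ellipsoid,
    map_rf_white_noise,
    measure_vstf,
    sinusoid_amplitude,
)
from midgetmosaic.wiring.surround import SurroundProfile, dog_model, DoGParams, fit_dog
from conftest import hex_grid, make_cone_mosaic


def _single(n, idx, w):
    return sparse.csr_matrix((np.atleast_1d(w), (np.atleast_1d(idx),
                                                 np.zeros(len(np.atleast_1d(idx)), int))),
                             shape=(n, 1))


class TestComputeResponses:
    def test_single_cone_center_weight_cancels(self):
        n = 5
        pc = _single(n, 2, 0.37)  # arbitrary weight
        C = np.zeros((n, 4))
        C[2] = [0.1, -0.2, 0.3, 0.0]
        r = compute_responses(C, pc).R_stim
        assert np.allclose(r[0], C[2])

    def test_uniform_contrast_closed_form(self):
        n = 20
        rng = np.random.default_rng(0)
        wc = rng.uniform(0.5, 1.0, n)
        ws = rng.uniform(0.0, 0.05, n)
        pc = sparse.csr_matrix(wc[:, None])
        ps = sparse.csr_matrix(ws[:, None])
        c = 0.3
        C = np.full((n, 1), c)
        rho = ws.sum() / wc.sum()
        r = compute_responses(C, pc, ps).R_stim
        assert r[0, 0] == pytest.approx(c * (1.0 - rho), rel=1e-12)

    def test_zero_contrast_zero_response(self):
        pc = _single(4, 1, 1.0)
        r = compute_responses(np.zeros((4, 3)), pc).R_stim
        assert np.all(r == 0.0)

    def test_superposition_exact(self):
        rng = np.random.default_rng(1)
        n = 30
        pc = sparse.csr_matrix(rng.uniform(0, 1, (n, 3)))
        ps = sparse.csr_matrix(rng.uniform(0, 0.1, (n, 3)))
        A = rng.normal(size=(n, 5))
        B = rng.normal(size=(n, 5))
        ra = compute_responses(A, pc, ps).R_stim
        rb = compute_responses(B, pc, ps).R_stim
        rab = compute_responses(A + B, pc, ps).R_stim
        assert np.allclose(rab, ra + rb, atol=1e-12)

    def test_zero_center_weight_rejected(self):
        pc = sparse.csr_matrix(np.zeros((3, 1)))
        with pytest.raises(ZeroDivisionError):
            compute_responses(np.zeros((3, 1)), pc)


class TestMeasureVSTF:
    @pytest.fixture(scope="class")
    def patch(self):
        s = 0.02
        pts = hex_grid(s, 0.4, jitter=0.02, seed=40)
        types = np.zeros(len(pts), dtype=int)
        cm = make_cone_mosaic(pts, types, s)
        center = int(np.argmin(np.linalg.norm(pts, axis=1)))
        return cm, center

    def test_no_surround_is_lowpass(self, patch):
        cm, center = patch
        pc = _single(len(cm), center, 1.0)
        sf = np.concatenate([[0.0], np.geomspace(0.5, 30.0, 8)])
        amp = measure_vstf(cm, pc, None, OpticsModel("diffraction_limited"), sf)[0]
        assert np.all(np.diff(amp[1:]) <= 1e-9)

    def test_zero_frequency_amplitude_matches_closed_form(self, patch):
        cm, center = patch
        pc = _single(len(cm), center, 1.0)
        prof = SurroundProfile(0.01, 0.08, 0.05, 0.02)
        r = np.linalg.norm(cm.positions - cm.positions[center], axis=1)
        ws = prof(r)
        ws[ws < 0.005] = 0.0
        ps = sparse.csr_matrix(ws[:, None])
        rho = ws.sum()
        sf = np.concatenate([[0.0], np.geomspace(0.5, 30.0, 8)])
        contrast = 0.5
        amp = measure_vstf(cm, pc, ps, OpticsModel("diffraction_limited"), sf,
                           contrast=contrast)[0]
        assert amp[0] == pytest.approx(abs(1.0 - rho) * contrast, rel=0.02)


class TestWhiteNoiseMapping:
    @pytest.fixture(scope="class")
    def cell(self):
        """Multi-cone RF center (inner hex ring) so checks resolve it."""
        from scipy.spatial import cKDTree

        s = 0.02
        pts = hex_grid(s, 0.25, jitter=0.02, seed=50)
        types = np.zeros(len(pts), dtype=int)
        types[::9] = 2
        cm = make_cone_mosaic(pts, types, s)
        center = int(np.argmin(np.linalg.norm(pts, axis=1)))
        _, ring = cKDTree(pts).query(pts[center], k=7)
        ring = [i for i in ring if types[i] != 2]
        n = len(pts)
        pc = sparse.csr_matrix((np.ones(len(ring)), (ring, [0] * len(ring))),
                               shape=(n, 1))
        prof = SurroundProfile(0.015, 0.1, 0.05, 0.03)
        mu = pts[ring].mean(axis=0)
        r = np.linalg.norm(pts - mu, axis=1)
        ws = prof(r)
        ws[cm.types == 2] = 0.0
        ws[ws < 0.005] = 0.0
        ps = sparse.csr_matrix(ws[:, None])
        return cm, pc, ps, center

    REGION = (-0.26, 0.26, -0.26, 0.26)

    def test_map_recovers_projected_pooling_weights(self, cell):
        cm, pc, ps, center = cell
        h = 0.02  # checks well below the multi-cone center diameter (~0.06)
        maps = map_rf_white_noise(cm, pc, ps, OpticsModel("diffraction_limited"),
                                  [0], self.REGION, check_size_deg=h,
                                  n_frames=5000, seed=3)
        m = maps[0]
        # project true center-minus-surround weights onto the check grid,
        # spreading each cone's weight by its aperture convolved with an
        # independently derived Gaussian equivalent of the Airy PSF
        from scipy.special import erf

        f = np.linspace(0.01, 120.0, 4000)
        fc = 3e-3 / 550e-9 * np.pi / 180.0
        nu = np.clip(f / fc, 0.0, 1.0)
        mtf = (2 / np.pi) * (np.arccos(nu) - nu * np.sqrt(1 - nu**2))
        f50 = np.interp(-0.5, -mtf, f)
        sig_psf = np.sqrt(np.log(2.0) / 2.0) / (np.pi * f50)
        w = np.asarray((pc - ps).todense()).ravel()
        truth = np.zeros_like(m.values)
        for i in np.flatnonzero(w):
            sig = np.sqrt(cm.aperture_sigma[i] ** 2 + sig_psf**2) * np.sqrt(2.0)
            gx = 0.5 * (erf((m.x_deg + h / 2 - cm.positions[i, 0]) / sig)
                        - erf((m.x_deg - h / 2 - cm.positions[i, 0]) / sig))
            gy = 0.5 * (erf((m.y_deg + h / 2 - cm.positions[i, 1]) / sig)
                        - erf((m.y_deg - h / 2 - cm.positions[i, 1]) / sig))
            truth += w[i] * np.outer(gy, gx)
        # correlate over the RF support (where the ground truth projects)
        support = np.abs(truth) > 1e-4 * np.abs(truth).max()
        r = np.corrcoef(truth[support], m.values[support])[0, 1]
        assert r > 0.95

    def test_no_surround_no_negative_lobe(self, cell):
        cm, pc, ps, center = cell
        maps = map_rf_white_noise(cm, pc, None, OpticsModel("diffraction_limited"),
                                  [0], self.REGION, check_size_deg=0.01,
                                  n_frames=3000, seed=4)
        m = maps[0]
        # max-statistic over ~2700 checks: use a 4-sigma bound on the floor
        assert abs(m.values.min()) < 4.0 * m.noise_floor

    def test_linearity_in_stimulus_contrast(self, cell):
        cm, pc, ps, center = cell
        a = map_rf_white_noise(cm, pc, ps, OpticsModel("diffraction_limited"),
                               [0], self.REGION, 0.01, n_frames=1500, seed=5,
                               contrast=0.25)[0]
        b = map_rf_white_noise(cm, pc, ps, OpticsModel("diffraction_limited"),
                               [0], self.REGION, 0.01, n_frames=1500, seed=5,
                               contrast=0.5)[0]
        assert np.allclose(b.values, 2.0 * a.values, atol=1e-12)

    def test_s_cone_positions_are_zero_sensitivity_spots(self, cell):
        cm, pc, ps, center = cell
        maps = map_rf_white_noise(cm, pc, ps, OpticsModel("diffraction_limited"),
                                  [0], self.REGION, 0.01, n_frames=2000, seed=6)
        m = maps[0]
        # checks containing only S cones near the center must sit at noise level
        s_idx = np.flatnonzero((cm.types == 2)
                               & (np.linalg.norm(cm.positions - cm.positions[center],
                                                 axis=1) < 0.06))
        assert len(s_idx) > 0
        for i in s_idx:
            ix = int((cm.positions[i, 0] - self.REGION[0]) / 0.01)
            iy = int((cm.positions[i, 1] - self.REGION[2]) / 0.01)
            assert abs(m.values[iy, ix]) < 6.0 * m.noise_floor


class TestEllipseFit:
    def _gaussian_map(self, sx, sy, theta=0.0, n=81, extent=0.5):
        xs = np.linspace(-extent, extent, n)
        xx, yy = np.meshgrid(xs, xs)
        u = xx * np.cos(theta) + yy * np.sin(theta)
        v = -xx * np.sin(theta) + yy * np.cos(theta)
        vals = np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))
        return RFMap(vals, xs, xs, "retinal_space")

    def test_isotropic_diameter(self):
        e = fit_ellipsoid(self._gaussian_map(0.1, 0.1))
        assert e.diameter == pytest.approx(0.2, rel=0.01)

    def test_anisotropic_diameter_formula(self):
        e = fit_ellipsoid(self._gaussian_map(0.16, 0.04, theta=0.4))
        assert e.diameter == pytest.approx(2 * np.sqrt(0.04 * 0.16), rel=0.02)
        assert e.sigma_major == pytest.approx(0.16, rel=0.02)
        assert e.sigma_minor == pytest.approx(0.04, rel=0.02)
        assert e.orientation_deg == pytest.approx(np.degrees(0.4), abs=3.0)

    def test_no_positive_lobe_rejected(self):
        xs = np.linspace(-1, 1, 21)
        with pytest.raises(ValueError):
            fit_ellipsoid(RFMap(-np.ones((21, 21)), xs, xs, "retinal_space"))


class TestRetinalVsVisualSpace:
    def test_optical_blur_enlarges_and_orients_the_rf(self):
        """A peripheral cell mapped through elongated optics must show a
        larger ellipse aligned with the blur axis."""
        s = 0.025
        pts = hex_grid(s, 0.3, jitter=0.02, seed=60)
        cm = make_cone_mosaic(pts, np.zeros(len(pts), int), s)
        center = int(np.argmin(np.linalg.norm(pts, axis=1)))
        pc = _single(len(cm), center, 1.0)
        region = (-0.31, 0.31, -0.31, 0.31)
        retinal = map_rf_white_noise(cm, pc, None, OpticsModel("diffraction_limited"),
                                     [0], region, 0.02, n_frames=4000, seed=7)[0]
        optics = OpticsModel("simplified_physiological", eccentricity_deg=(0.0, 8.0))
        visual = map_rf_white_noise(cm, pc, None, optics, [0], region, 0.02,
                                    n_frames=4000, seed=7)[0]
        er = fit_ellipsoid(retinal)
        ev = fit_ellipsoid(visual)
        assert ev.sigma_major * ev.sigma_minor >= er.sigma_major * er.sigma_minor
        sig_maj, sig_min = optics.blur_sigmas()
        assert sig_maj / sig_min > 1.5
        axis = optics.elongation_axis_deg  # 90 deg (radial, cell above fovea)
        diff = abs((ev.orientation_deg - axis + 90) % 180 - 90)
        assert diff < 15.0


class TestDoGInferenceCritique:
    def test_good_dog_fit_but_misleading_surround_inference(self, single_cone_cell):
        """The DoG fit to a retinal-space transfer function can be excellent
        while inferring a surround that is more diffuse and weaker-peaked
        than the true double-exponential pooling."""
        from midgetmosaic.wiring.center import CenterConnectivity
        from midgetmosaic.wiring.surround import ForwardCell

        cm, mrgc, pc = single_cone_cell
        conn = CenterConnectivity(pc, "2C")
        sf = np.concatenate([[0.0], np.geomspace(0.2, 30.0, 9)])
        fwd = ForwardCell(0, cm, mrgc, conn, OpticsModel("diffraction_limited"),
                          sf, patch_radius=0.34)
        true_prof = SurroundProfile(0.015, 0.06, 0.06, 0.02)
        vstf = fwd.vstf(true_prof)
        fit, rms = fit_dog(sf, vstf)
        assert rms < 0.05 * vstf.max()
        # peak-to-integral concentration: inferred Gaussian surround vs truth
        inferred_conc = 1.0 / (np.pi * fit.Rs**2)
        true_conc = (true_prof(0.0) / true_prof.integrated)
        assert inferred_conc < true_conc


def test_sinusoid_amplitude_exact_on_pure_tone():
    t = np.arange(16)
    r = 0.37 * np.sin(2 * np.pi * t / 16 + 1.1)
    assert sinusoid_amplitude(r[None, :])[0] == pytest.approx(0.37, rel=1e-12)
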