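"""Surround pooling: DoG model/fit, double-exponential profiles, optimization."""

import numpy as np
import pytest
from scipy import sparse

from midgetmosaic.response import compute_responses, sinusoid_amplitude
from midgetmosaic.wiring.surround import (
    DoGParams,
    ForwardCell,
    SurroundProfile,
    TargetRatios,
    build_pooling_grid,
    default_h1_bounds,
    dog_model,
    evaluate_surround_weights,
    fit_dog,
    interpolate_surrounds,
    jitter_integrated_ratio,
    optimize_surround,
)
from midgetmosaic.wiring.center import CenterConnectivity
from midgetmosaic.frontend.optics import OpticsModel
from conftest import hex_grid, make_cone_mosaic

SF = np.concatenate([[0.0], np.geomspace(0.2, 30.0, 9)])


class TestDoGModel:
    def test_zero_frequency_closed_form(self):
        p = DoGParams(Kc=2.0, Ks=0.1, Rc=0.05, Rs=0.3)
        assert dog_model(0.0, p) == pytest.approx(2.0 * 0.05**2 - 0.1 * 0.3**2)

    def test_center_only_is_gaussian_transfer(self):
        p = DoGParams(Kc=1.0, Ks=1e-300, Rc=1.0, Rs=2.0)
        w = np.array([0.0, 0.3, 0.7])
        assert np.allclose(dog_model(w, p), np.exp(-((np.pi * w) ** 2)), atol=1e-12)

    def test_matches_arbitrary_precision_oracle(self):
        import sympy as sp

        p = DoGParams(Kc=1.0, Ks=0.005, Rc=0.05, Rs=0.3)
        w = sp.Rational(1)
        expr = (sp.Float(1, 30) * sp.Rational(1, 400)
                * sp.exp(-((sp.pi * sp.Rational(5, 100) * w) ** 2))
                - sp.Rational(5, 1000) * sp.Rational(9, 100)
                * sp.exp(-((sp.pi * sp.Rational(3, 10) * w) ** 2)))
        oracle = float(sp.N(expr, 30))
        assert dog_model(1.0, p) == pytest.approx(oracle, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            DoGParams(Kc=1.0, Ks=0.1, Rc=0.3, Rs=0.2)  # Rs <= Rc
        with pytest.raises(ValueError):
            DoGParams(Kc=-1.0, Ks=0.1, Rc=0.1, Rs=0.2)


class TestFitDoG:
    TRUE = DoGParams(Kc=80.0, Ks=1.2, Rc=0.04, Rs=0.28)

    def test_unconstrained_recovery_from_noiseless_data(self):
        w = np.geomspace(0.1, 40.0, 14)
        y = dog_model(w, self.TRUE)
        fit, rms = fit_dog(w, y)
        assert fit.Rc == pytest.approx(self.TRUE.Rc, rel=0.01)
        assert fit.Rs == pytest.approx(self.TRUE.Rs, rel=0.01)
        assert fit.Kc == pytest.approx(self.TRUE.Kc, rel=0.03)
        assert fit.Ks == pytest.approx(self.TRUE.Ks, rel=0.03)

    def test_constraints_centered_on_truth_preserve_recovery(self):
        w = np.geomspace(0.1, 40.0, 14)
        y = dog_model(w, self.TRUE)
        targets = TargetRatios(radius_ratio_mean=self.TRUE.radius_ratio,
                               integrated_ratio_mean=self.TRUE.integrated_ratio)
        fit, rms = fit_dog(w, y, targets)
        assert fit.Rc == pytest.approx(self.TRUE.Rc, rel=0.01)
        assert rms == pytest.approx(0.0, abs=1e-8 * y.max())

    def test_out_of_band_data_clamps_to_band_edge(self):
        w = np.geomspace(0.1, 40.0, 14)
        y = dog_model(w, self.TRUE)  # radius ratio 7.0
        targets = TargetRatios(radius_ratio_mean=3.0, band_width=1.2,
                               integrated_ratio_mean=self.TRUE.integrated_ratio)
        fit, rms = fit_dog(w, y, targets)
        assert fit.radius_ratio == pytest.approx(3.0 * 1.2, rel=1e-3)
        _, rms_free = fit_dog(w, y)
        assert rms > rms_free

    def test_degenerate_inputs_rejected(self):
        w = np.geomspace(0.1, 40.0, 14)
        with pytest.raises(ValueError):
            fit_dog(w, np.zeros_like(w))
        with pytest.raises(ValueError):
            fit_dog(np.linspace(1.0, 2.0, 8), np.ones(8))  # < 1.5 decades


class TestSurroundWeights:
    PROF = SurroundProfile(K_wide=0.02, R_wide=0.2, K_narrow=0.3, R_narrow=0.04)

    def test_profile_value_identities(self):
        assert self.PROF(0.0) == pytest.approx(0.32)
        near_pure_wide = SurroundProfile(0.02, 0.2, 1e-12, 0.04)
        assert near_pure_wide(0.2) == pytest.approx(0.02 / np.e, rel=1e-6)
        r = np.linspace(0.0, 0.5, 100)
        assert np.all(np.diff(self.PROF(r)) < 0)

    def test_component_order_normalized(self):
        p = SurroundProfile(K_wide=0.3, R_wide=0.04, K_narrow=0.02, R_narrow=0.2)
        assert p.R_wide > p.R_narrow

    def test_s_cones_zero_and_pruning(self):
        pts = hex_grid(0.02, 0.2)
        types = np.zeros(len(pts), dtype=int)
        types[::7] = 2  # scatter S cones
        cm = make_cone_mosaic(pts, types, 0.02)
        w = evaluate_surround_weights(self.PROF, np.zeros(2), cm,
                                      peak_center_weight=1.0)
        assert np.all(w[types == 2] == 0.0)
        nz = w[w > 0]
        assert np.all(nz >= 0.005)


def _ideal_vstf(weights_c, weights_s, positions, sf_list, n_phases=16):
    """Transfer amplitudes for explicit pooling weights under delta optics."""
    n = len(positions)
    pc = sparse.csr_matrix((weights_c, (np.arange(n), np.zeros(n, int))),
                           shape=(n, 1))
    ps = sparse.csr_matrix((weights_s, (np.arange(n), np.zeros(n, int))),
                           shape=(n, 1))
    amps = []
    for w in sf_list:
        t = np.arange(n_phases)
        C = np.sin(2 * np.pi * (w * positions[:, 1][:, None]) + 2 * np.pi * t / n_phases)
        amps.append(sinusoid_amplitude(compute_responses(C, pc, ps).R_stim)[0])
    return np.asarray(amps)


def test_gaussian_center_surround_reproduces_dog_analytically():
    """Forward-consistency oracle: exact Gaussian pooling under delta optics
    must reproduce the Difference-of-Gaussians transfer within 1%."""
    s = 0.02
    pts = hex_grid(s, 0.6)
    r = np.linalg.norm(pts, axis=1)
    Rc, Rs, ir = 0.05, 0.2, 0.6
    wc = np.exp(-(r / Rc) ** 2)
    ws = ir * (Rc / Rs) ** 2 * np.exp(-(r / Rs) ** 2)
    sf = np.concatenate([[0.0], np.geomspace(0.3, 12.0, 10)])
    sim = _ideal_vstf(wc, ws, pts, sf)
    dog = np.abs(dog_model(sf, DoGParams(1.0, ir * (Rc / Rs) ** 2 / 1.0, Rc, Rs)))
    sim_n = sim / sim[0]
    dog_n = dog / dog[0]
    assert np.all(np.abs(sim_n - dog_n) <= 0.01 * dog_n.max())


@pytest.fixture(scope="module")
def fwd_cell(single_cone_cell):
    cm, mrgc, pc = single_cone_cell
    conn = CenterConnectivity(pc, "2C")
    return ForwardCell(0, cm, mrgc, conn, OpticsModel("diffraction_limited"),
                       SF, patch_radius=0.34)


class TestOptimizeSurround:
    # a clearly bandpass operating point whose unconstrained DoG fit is stable
    TRUE = SurroundProfile(K_wide=0.015, R_wide=0.06, K_narrow=0.06, R_narrow=0.02)

    def _bounds(self):
        return {
            "K_wide": (1.5e-3, 0.15), "R_wide": (0.03, 0.2),
            "K_narrow": (6e-3, 0.6), "R_narrow": (0.008, 0.06),
        }

    def _self_targets(self, fwd):
        vstf = fwd.vstf(self.TRUE)
        fit, _ = fit_dog(fwd.sf_list, vstf)
        return TargetRatios(radius_ratio_mean=fit.radius_ratio,
                            integrated_ratio_mean=fit.integrated_ratio), vstf

    def test_self_consistent_recovery_within_2_percent(self, single_cone_cell,
                                                       fwd_cell):
        cm, mrgc, pc = single_cone_cell
        targets, vstf_true = self._self_targets(fwd_cell)
        conn = CenterConnectivity(pc, "2C")
        prof, diag = optimize_surround(
            0, cm, mrgc, conn, OpticsModel("diffraction_limited"), targets,
            h1_bounds=self._bounds(), sf_list=SF, seed=0, n_restarts=2,
            extra_start_profiles=(self.TRUE,))
        vstf_rec = fwd_cell.vstf(prof)
        scale = np.max(np.abs(vstf_true))
        assert np.all(np.abs(vstf_rec - vstf_true) <= 0.02 * scale)
        assert diag["converged"]

    def test_collapsed_bounds_return_that_point(self, single_cone_cell):
        cm, mrgc, pc = single_cone_cell
        conn = CenterConnectivity(pc, "2C")
        point = {k: (v, v) for k, v in
                 {"K_wide": 0.015, "R_wide": 0.06, "K_narrow": 0.06,
                  "R_narrow": 0.02}.items()}
        prof, diag = optimize_surround(
            0, cm, mrgc, conn, OpticsModel("diffraction_limited"),
            TargetRatios(), h1_bounds=point, sf_list=SF)
        assert (prof.K_wide, prof.R_wide, prof.K_narrow, prof.R_narrow) == (
            0.015, 0.06, 0.06, 0.02)
        assert diag["n_eval"] == 1

    def test_widening_target_band_never_increases_residual(self, single_cone_cell,
                                                           fwd_cell):
        cm, mrgc, pc = single_cone_cell
        conn = CenterConnectivity(pc, "2C")
        targets, _ = self._self_targets(fwd_cell)
        results = {}
        prev_profile = None
        for band in (1.1, 1.35, 1.7):
            t = TargetRatios(radius_ratio_mean=targets.radius_ratio_mean,
                             integrated_ratio_mean=targets.integrated_ratio_mean,
                             band_width=band)
            extra = (self.TRUE,) if prev_profile is None else (self.TRUE, prev_profile)
            prof, diag = optimize_surround(
                0, cm, mrgc, conn, OpticsModel("diffraction_limited"), t,
                h1_bounds=self._bounds(), sf_list=SF, seed=1, n_restarts=1,
                maxiter=100, extra_start_profiles=extra)
            results[band] = diag["relative_residual"]
            prev_profile = prof
        assert results[1.35] <= results[1.1] + 1e-9
        assert results[1.7] <= results[1.35] + 1e-9


class TestPoolingGridAndInterpolation:
    def _patch_with_numerosity(self, n_per_center, n_centers_side=4):
        """Explicit connectivity with a fixed cone numerosity per center."""
        s = 0.02
        pts = hex_grid(s, 0.4, jitter=0.02, seed=30)
        rng = np.random.default_rng(31)
        types = (rng.random(len(pts)) < 1 / 3).astype(int)
        cm = make_cone_mosaic(pts, types, s)
        from scipy.spatial import cKDTree

        tree = cKDTree(pts)
        centers = hex_grid(s * 2.5, 0.25, seed=32)[: n_centers_side**2]
        rows, cols = [], []
        used = set()
        mrgc = []
        for k, c in enumerate(centers):
            _, idx = tree.query(c, k=12)
            take = [i for i in idx if i not in used][:n_per_center]
            if len(take) < n_per_center:
                continue
            used.update(take)
            rows.extend(take)
            cols.extend([len(mrgc)] * n_per_center)
            mrgc.append(pts[take].mean(axis=0))
        w = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)),
                              shape=(len(pts), len(mrgc)))
        return cm, np.asarray(mrgc), CenterConnectivity(w, "2C")

    POINT = {"K_wide": (0.006, 0.006), "R_wide": (0.15, 0.15),
             "K_narrow": (0.05, 0.05), "R_narrow": (0.03, 0.03)}

    def test_single_node_uniform_numerosity_gives_two_profiles(self):
        cm, mrgc, conn = self._patch_with_numerosity(1)
        grid = build_pooling_grid(cm, mrgc, conn, OpticsModel("diffraction_limited"),
                                  TargetRatios(), h1_bounds=self.POINT, n_xy=1,
                                  sf_list=SF)
        assert len(grid.nodes) == 1
        assert len(grid.profiles) == 2  # 1 node x 1 numerosity x {L, M}
        assert grid.numerosities_at(0) == [1]

    def test_mixed_numerosity_grid_counting_rule(self):
        cm2, m2, c2 = self._patch_with_numerosity(2)
        cm3, m3, c3 = self._patch_with_numerosity(3)
        # merge the two connectivities onto one cone mosaic
        w = sparse.hstack([c2.weights, c3.weights]).tocsr()
        mrgc = np.vstack([m2, m3])
        conn = CenterConnectivity(w, "2C")
        grid = build_pooling_grid(cm2, mrgc, conn, OpticsModel("diffraction_limited"),
                                  TargetRatios(), h1_bounds=self.POINT, n_xy=2,
                                  sf_list=SF, cells_per_node=len(mrgc))
        assert len(grid.nodes) == 2
        assert len(grid.profiles) == 2 * 2 * 2  # nodes x numerosities x dominance

    def test_interpolation_collapses_at_node_for_pure_l_cell(self):
        cm, mrgc, conn = self._patch_with_numerosity(1)
        # make every cone L so dominance is unambiguous
        cm.types[:] = 0
        grid = build_pooling_grid(cm, mrgc, conn, OpticsModel("diffraction_limited"),
                                  TargetRatios(), h1_bounds=self.POINT, n_xy=1,
                                  sf_list=SF)
        ps = interpolate_surrounds(cm, mrgc, conn, grid)
        prof = grid.profiles[(0, 1, "L")]
        pc = conn.weights.tocsc()
        k = 0
        idx = pc.indices[pc.indptr[k]:pc.indptr[k + 1]]
        cent = cm.positions[idx].mean(axis=0)
        direct = evaluate_surround_weights(prof, cent, cm, 1.0)
        # spatial and spectral weights collapse; only the ON-positivity cap
        # (documented surround/center <= 0.95) may rescale the column
        pc_tot = float(pc.data[pc.indptr[k]:pc.indptr[k + 1]].sum())
        scale = min(1.0, 0.95 * pc_tot / direct.sum())
        col = np.asarray(ps[:, k].todense()).ravel()
        assert np.allclose(col, scale * direct, rtol=1e-9)


class TestJitter:
    def _population(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        n_cones = 50 * n
        rows = np.arange(n_cones)
        cols = np.repeat(np.arange(n), 50)
        pc = sparse.csr_matrix((np.ones(n_cones), (rows, cols)), shape=(n_cones, n))
        base = rng.uniform(0.4, 0.6, n_cones)  # integrated ratio ~ 0.5
        ps = sparse.csr_matrix((base, (rows, cols)), shape=(n_cones, n))
        return pc, ps

    def test_zero_target_variance_is_identity(self):
        pc, ps = self._population()
        t = TargetRatios(integrated_ratio_variance=0.0)
        out, m = jitter_integrated_ratio(ps, pc, t, seed=1)
        assert np.allclose(m, 1.0)
        assert (out != ps.tocsr()).nnz == 0

    def test_moment_matching_on_500_cells(self):
        pc, ps = self._population(n=500, seed=2)
        t = TargetRatios(integrated_ratio_variance=0.01)
        out, m = jitter_integrated_ratio(ps, pc, t, seed=3)
        rho0 = np.asarray(ps.sum(axis=0)).ravel() / np.asarray(pc.sum(axis=0)).ravel()
        rho1 = np.asarray(out.sum(axis=0)).ravel() / np.asarray(pc.sum(axis=0)).ravel()
        assert np.all(m > 0)
        assert rho1.var() == pytest.approx(0.01, rel=0.10)
        assert rho1.mean() == pytest.approx(rho0.mean(), rel=0.02)

    def test_radius_ratio_untouched_by_jitter(self):
        """The scalar multiplies surround strength (Ks and the integrated
        ratio) without changing Rs/Rc; verified by re-fitting the DoG model
        before and after on an exactly Gaussian center/surround cell, where
        the fit is well conditioned."""
        s = 0.02
        pts = hex_grid(s, 0.6)
        r = np.linalg.norm(pts, axis=1)
        Rc, Rs, ir = 0.05, 0.2, 0.45
        wc = np.exp(-(r / Rc) ** 2)
        ws = ir * (Rc / Rs) ** 2 * np.exp(-(r / Rs) ** 2)
        sf = np.concatenate([[0.0], np.geomspace(0.3, 12.0, 10)])
        v0 = _ideal_vstf(wc, ws, pts, sf)
        v1 = _ideal_vstf(wc, 1.3 * ws, pts, sf)
        f0, _ = fit_dog(sf, v0)
        f1, _ = fit_dog(sf, v1)
        assert f1.radius_ratio == pytest.approx(f0.radius_ratio, rel=0.02)
        assert f1.integrated_ratio == pytest.approx(1.3 * f0.integrated_ratio,
                                                    rel=0.02)
        assert f1.Rc == pytest.approx(f0.Rc, rel=0.02)

    def test_unreachable_variance_rejected(self):
        pc, ps = self._population()
        t = TargetRatios(integrated_ratio_variance=25.0)
        with pytest.raises(ValueError):
            jitter_integrated_ratio(ps, pc, t, seed=1)

    def test_small_population_rejected(self):
        pc, ps = self._population(n=10)
        with pytest.raises(ValueError):
            jitter_integrated_ratio(ps, pc, TargetRatios(), seed=1)


def test_default_h1_bounds_are_positive_and_ordered(fwd_cell):
    b = default_h1_bounds(fwd_cell, TargetRatios())
    for k, (lo, hi) in b.items():
        assert 0 < lo < hi
    assert b["R_narrow"][1] < b["R_wide"][1]
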