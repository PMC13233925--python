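"""End-to-end mosaic synthesis: lattices -> center wiring -> surround wiring."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .density import MeridianDensitySet, build_density_map
from .frontend.optics import OpticsModel
from .lattice import ConeMosaic, assign_cone_types, synthesize_lattice
from .wiring.center import (
    CenterConnectivity,
    ExponentSchedule,
    apply_divergence,
    connect_exclusive,
    refine_tradeoff,
)
from .wiring.surround import (
    TargetRatios,
    build_pooling_grid,
    interpolate_surrounds,
    jitter_integrated_ratio,
)

__all__ = ["Mosaic", "synthesize_mosaic"]

STAGES = ("1", "2A", "2B", "2C", "3")


@dataclass
class Mosaic:
    """A synthesized ON-midget mosaic with its cone input and connectivity."""

    cone_mosaic: ConeMosaic
    mrgc_positions: np.ndarray
    conn_center: CenterConnectivity | None = None
    P_surround: sparse.csr_matrix | None = None
    stage: str = "1"
    config: dict = field(default_factory=dict)
    jitter_multipliers: np.ndarray | None = None
    grid_diagnostics: dict = field(default_factory=dict)

    @property
    def P_center(self):
        return None if self.conn_center is None else self.conn_center.weights

    @property
    def n_cells(self) -> int:
        return len(self.mrgc_positions)

    def cell_eccentricities(self) -> np.ndarray:
        return np.hypot(self.mrgc_positions[:, 0], self.mrgc_positions[:, 1])


def synthesize_mosaic(
    region,
    seed: int = 0,
    stage: str = "3",
    phi: float = 1.0,
    optics: OpticsModel | None = None,
    targets: TargetRatios | None = None,
    max_iters: int = 150,
    l_to_m_ratio: float = 2.0,
    s_fraction: float = 0.07,
    s_exclusion_radius_deg: float = 0.15,
    n_xy: int | None = None,
    sf_list=None,
) -> Mosaic:
    """Synthesize a mosaic over ``region = (x0, x1, y0, y1)`` up to ``stage``.

    The cone lattice is synthesized over the region inflated by three local
    mRGC spacings so every RF center near the edge finds its cones.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    x0, x1, y0, y1 = region
    cfg = dict(region=tuple(region), seed=seed, stage=stage, phi=phi,
               l_to_m_ratio=l_to_m_ratio, s_fraction=s_fraction,
               s_exclusion_radius_deg=s_exclusion_radius_deg)
    pad_map = 0.25 * max(x1 - x0, y1 - y0) + 0.2
    on = MeridianDensitySet("on_mrgc_rf")
    cone = MeridianDensitySet("cone")
    dm_on = build_density_map(on, (x0 - pad_map, x1 + pad_map, y0 - pad_map, y1 + pad_map),
                              resolution=min(0.05, (x1 - x0) / 20))
    dm_cone = build_density_map(cone, (x0 - pad_map, x1 + pad_map, y0 - pad_map, y1 + pad_map),
                                resolution=min(0.05, (x1 - x0) / 20))
    mrgc_lat = synthesize_lattice(dm_on, region, seed=seed, max_iters=max_iters)
    # cones span the same region as the mRGC lattice: every L/M cone must join
    # a center, so a larger cone field would pile edge cones into border cells
    cone_lat = synthesize_lattice(dm_cone, region, seed=seed + 1,
                                  max_iters=max_iters)
    cm = assign_cone_types(cone_lat, l_to_m_ratio, s_fraction,
                           s_exclusion_radius_deg, seed=seed + 2)
    mosaic = Mosaic(cm, mrgc_lat.positions, stage="1", config=cfg)
    if stage == "1":
        return mosaic
    conn = connect_exclusive(cm, mrgc_lat.positions)
    mosaic.conn_center, mosaic.stage = conn, "2A"
    if stage == "2A":
        return mosaic
    conn = refine_tradeoff(conn, cm, mrgc_lat.positions, phi)
    mosaic.conn_center, mosaic.stage = conn, "2B"
    if stage == "2B":
        return mosaic
    conn = apply_divergence(conn, cm, mrgc_lat.positions, ExponentSchedule())
    mosaic.conn_center, mosaic.stage = conn, "2C"
    if stage == "2C":
        return mosaic
    cx, cy = 0.5 * (x0 + x1), 0.5 * (y0 + y1)
    optics = optics or OpticsModel("simplified_physiological",
                                   eccentricity_deg=(cx, cy))
    targets = targets or TargetRatios()
    grid = build_pooling_grid(cm, mrgc_lat.positions, conn, optics, targets,
                              n_xy=n_xy, sf_list=sf_list, seed=seed + 3)
    mosaic.grid_diagnostics = grid.diagnostics
    ps = interpolate_surrounds(cm, mrgc_lat.positions, conn, grid)
    if mosaic.n_cells >= 30:
        ps, mult = jitter_integrated_ratio(ps, conn.weights, targets,
                                           seed=seed + 4,
                                           cell_ecc=mosaic.cell_eccentricities())
    else:
        mult = np.ones(mosaic.n_cells)
    mosaic.P_surround = ps
    mosaic.jitter_multipliers = mult
    mosaic.stage = "3"
    return mosaic
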