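"""Shared fixtures: small synthetic mosaics with controlled density ratios."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import sparse

from midgetmosaic.density import DensityMap
from midgetmosaic.lattice import ConeMosaic, PositionLattice


def hex_grid(spacing, half_width, jitter=0.0, seed=0):
    """Hexagonal points covering a square of the given half width."""
    rng = np.random.default_rng(seed)
    rows = []
    n = int(np.ceil(half_width / (spacing * np.sqrt(3) / 2))) + 1
    for j in range(-n, n + 1):
        y = j * spacing * np.sqrt(3) / 2
        if abs(y) > half_width:
            continue
        x = np.arange(-half_width - spacing, half_width + spacing, spacing)
        x = x + (spacing / 2 if j % 2 else 0.0)
        keep = np.abs(x) <= half_width
        rows.append(np.stack([x[keep], np.full(keep.sum(), y)], axis=1))
    pts = np.concatenate(rows)
    if jitter:
        pts = pts + rng.normal(0, jitter * spacing, pts.shape)
    return pts


def make_cone_mosaic(pts, types, spacing):
    """ConeMosaic from explicit positions/types with uniform spacing."""
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    lat = PositionLattice(pts, "cone", 0, 0,
                          (pts[:, 0].min(), pts[:, 0].max(),
                           pts[:, 1].min(), pts[:, 1].max()))
    sp = np.full(n, spacing)
    return ConeMosaic(lat, np.asarray(types, dtype=int), 0.79 * sp, sp)


@pytest.fixture(scope="session")
def uniform_map():
    xs = np.linspace(-1.0, 1.0, 5)
    return DensityMap(xs, xs, np.full((5, 5), 1000.0), "cone", None)


@pytest.fixture(scope="session")
def matched_patch():
    """Fovea-like fixture: equal cone and mRGC densities, no S cones.

    Offsetting the two hexagonal lattices by half a spacing gives each center
    a unique nearest cone (bijection under exclusive wiring).
    """
    s = 0.02
    cones = hex_grid(s, 0.3, jitter=0.04, seed=1)
    rng = np.random.default_rng(2)
    types = (rng.random(len(cones)) < 1 / 3).astype(int)  # 2:1 L:M
    cm = make_cone_mosaic(cones, types, s)
    mrgc = cones + np.array([s / 2, s / 4])
    return cm, mrgc


@pytest.fixture(scope="session")
def ratio3_patch():
    """Peripheral-like fixture: L/M cone density three times mRGC density."""
    s = 0.02
    cones = hex_grid(s, 0.4, jitter=0.05, seed=3)
    rng = np.random.default_rng(4)
    types = (rng.random(len(cones)) < 1 / 3).astype(int)
    cm = make_cone_mosaic(cones, types, s)
    mrgc = hex_grid(s * np.sqrt(3.0), 0.36, jitter=0.05, seed=5)
    return cm, mrgc


@pytest.fixture(scope="session")
def single_cone_cell():
    """One-cone-center cell on a hex cone patch, for surround experiments."""
    s = 0.02
    cones = hex_grid(s, 0.35, jitter=0.03, seed=7)
    rng = np.random.default_rng(8)
    types = (rng.random(len(cones)) < 1 / 3).astype(int)
    cm = make_cone_mosaic(cones, types, s)
    center_cone = int(np.argmin(np.linalg.norm(cones, axis=1)))
    types[center_cone] = 0  # make the center cone an L cone
    n = len(cones)
    pc = sparse.csr_matrix(([1.0], ([center_cone], [0])), shape=(n, 1))
    mrgc = cones[center_cone][None, :]
    return cm, mrgc, pc
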