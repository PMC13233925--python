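"""Cone-to-RF-center wiring (stage 2).

Stage 2A partitions the L/M cones exclusively among the mRGC RF centers
(nearest-center seeding, empty-center repair, then local load-balancing
transfers that shrink the total within-center spread). Stage 2B refines the
partition by pairwise swaps between neighboring centers under a single
tradeoff parameter phi: phi = 1 maximizes spatial compactness, phi = 0
maximizes spectral purity. Stage 2C lifts exclusivity: each center pools
cones with a supra-Gaussian radial profile exp[-0.5 (r/sigma_k)^alpha] whose
exponent alpha falls from 10 (flat-top, non-overlapping) in central retina
to 2 (Gaussian, overlapping) beyond 15 degrees.

S cones are never connected. At stages 2A/2B every L/M cone carries unit
weight in exactly one center; at 2C weights are graded and a cone may serve
several centers. All tie-breaks go to the lowest cell index, so the wiring
is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import Delaunay, cKDTree

from ..lattice import ConeMosaic, S

__all__ = [
    "CenterConnectivity",
    "ExponentSchedule",
    "exponent_schedule",
    "connect_exclusive",
    "refine_tradeoff",
    "apply_divergence",
    "center_members",
    "center_purity",
    "center_spread",
    "overlap_stats",
]


@dataclass
class CenterConnectivity:
    """Sparse cone-to-center weights P_center(i, k)."""

    weights: sparse.csr_matrix  # (n_cones, n_cells)
    stage: str
    phi: float | None = None

    @property
    def n_cones(self) -> int:
        return self.weights.shape[0]

    @property
    def n_cells(self) -> int:
        return self.weights.shape[1]

    def assignment(self) -> np.ndarray:
        """Per-cone center index at exclusive stages (-1 for unconnected cones)."""
        w = self.weights.tocsr()
        out = np.full(self.n_cones, -1, dtype=int)
        for i in range(self.n_cones):
            cols = w.indices[w.indptr[i]:w.indptr[i + 1]]
            if len(cols):
                out[i] = cols[np.argmax(w.data[w.indptr[i]:w.indptr[i + 1]])]
        return out


@dataclass
class ExponentSchedule:
    """Supra-Gaussian exponent vs eccentricity: 10 up to 7 deg, 2 beyond 15 deg.

    Between the breakpoints the exponent follows a smooth half-cosine ramp
    (the endpoints and monotonicity are the constrained features).
    """

    flat_until_deg: float = 7.0
    asymptote_deg: float = 15.0
    central_value: float = 10.0
    peripheral_value: float = 2.0

    def __call__(self, ecc_deg):
        e = np.asarray(ecc_deg, dtype=float)
        if np.any(e < 0):
            raise ValueError("eccentricity must be non-negative")
        t = np.clip((e - self.flat_until_deg) / (self.asymptote_deg - self.flat_until_deg),
                    0.0, 1.0)
        ramp = 0.5 + 0.5 * np.cos(np.pi * t)
        out = self.peripheral_value + (self.central_value - self.peripheral_value) * ramp
        return float(out) if np.isscalar(ecc_deg) else out


def exponent_schedule(ecc_deg):
    """Default eccentricity-varying supra-Gaussian exponent."""
    return ExponentSchedule()(ecc_deg)


# ---------------------------------------------------------------------------
# stage 2A


def _lm_indices(mosaic: ConeMosaic) -> np.ndarray:
    return np.flatnonzero(mosaic.types != S)


def connect_exclusive(cone_mosaic: ConeMosaic, mrgc_positions: np.ndarray,
                      max_passes: int = 30) -> CenterConnectivity:
    """Stage 2A: every L/M cone joins exactly one RF center; no center is empty."""
    mrgc_positions = np.asarray(mrgc_positions, dtype=float)
    lm = _lm_indices(cone_mosaic)
    n_cells = len(mrgc_positions)
    if len(lm) < n_cells:
        raise ValueError(
            f"assignment infeasible: {len(lm)} L/M cones for {n_cells} centers")
    cone_xy = cone_mosaic.positions[lm]
    tree = cKDTree(mrgc_positions)
    _, assign = tree.query(cone_xy)
    counts = np.bincount(assign, minlength=n_cells)
    # repair empty centers: steal the nearest cone held by a multi-cone center;
    # remaining empties are filled by the load-balancing passes, which treat
    # an empty neighbor as an unconditional recipient (deficits propagate
    # across the partition in a few passes)
    cone_tree = cKDTree(cone_xy)
    for k in np.flatnonzero(counts == 0):
        for j in cone_tree.query(mrgc_positions[k], k=min(len(lm), 64))[1]:
            if counts[assign[j]] >= 2:
                counts[assign[j]] -= 1
                assign[j] = k
                counts[k] += 1
                break
    assign = _balance(cone_xy, assign, counts, mrgc_positions, max_passes)
    if np.any(np.bincount(assign, minlength=n_cells) == 0):
        k = int(np.argmin(np.bincount(assign, minlength=n_cells)))
        raise ValueError(f"could not populate RF center {k}")
    rows = lm
    w = sparse.csr_matrix(
        (np.ones(len(lm)), (rows, assign)), shape=(len(cone_mosaic), n_cells))
    return CenterConnectivity(w, "2A")


def _neighbor_pairs(mrgc_positions: np.ndarray) -> np.ndarray:
    if len(mrgc_positions) < 4:
        k = len(mrgc_positions)
        return np.array([(i, j) for i in range(k) for j in range(i + 1, k)], dtype=int)
    tri = Delaunay(mrgc_positions)
    e = np.concatenate([tri.simplices[:, [0, 1]], tri.simplices[:, [1, 2]],
                        tri.simplices[:, [0, 2]]])
    return np.unique(np.sort(e, axis=1), axis=0)


def _fill_empties(cone_xy, assign, counts, members, mrgc_positions, nbrs):
    """Populate empty centers by shifting cones along shortest neighbor paths
    from the nearest multi-cone center (one relocation per hop)."""
    from collections import deque

    while True:
        empties = np.flatnonzero(counts == 0)
        if len(empties) == 0:
            return
        t = int(empties[0])
        prev = {t: None}
        queue = deque([t])
        found = None
        while queue:
            u = queue.popleft()
            if counts[u] >= 2:
                found = u
                break
            for v in sorted(nbrs[u]):
                if v not in prev:
                    prev[v] = u
                    queue.append(v)
        if found is None:
            raise ValueError(f"could not populate RF center {t}")
        u = found
        while prev[u] is not None:
            b = prev[u]
            mem = members[u]
            j = mem[int(np.argmin(np.linalg.norm(
                cone_xy[mem] - mrgc_positions[b], axis=1)))]
            members[u].remove(j)
            members[b].append(j)
            assign[j] = b
            counts[u] -= 1
            counts[b] += 1
            u = b


def _balance(cone_xy, assign, counts, mrgc_positions, max_passes):
    """Move peripheral cones from crowded centers to under-loaded neighbors
    whenever that shrinks the total within-center spread about cone centroids."""
    n_cells = len(mrgc_positions)
    pairs = _neighbor_pairs(mrgc_positions)
    nbrs = [[] for _ in range(n_cells)]
    for a, b in pairs:
        nbrs[a].append(b)
        nbrs[b].append(a)
    members = [list(np.flatnonzero(assign == k)) for k in range(n_cells)]
    _fill_empties(cone_xy, assign, counts, members, mrgc_positions, nbrs)
    sums = np.zeros((n_cells, 2))
    np.add.at(sums, assign, cone_xy)
    for _ in range(max_passes):
        moved = False
        for k in range(n_cells):
            if counts[k] < 2:
                continue
            under = [n for n in sorted(nbrs[k]) if counts[k] - counts[n] >= 2]
            if not under:
                continue
            mu_k = sums[k] / counts[k]
            mem = members[k]
            far = mem[int(np.argmax(np.linalg.norm(cone_xy[mem] - mu_k, axis=1)))]
            c = cone_xy[far]
            best, best_d = -1, 0.0
            for n in under:
                if counts[n] == 0:
                    # an empty center must be populated regardless of spread;
                    # prefer the nearest empty neighbor
                    d_gain = -1e18 - 1.0 / (1.0 + np.sum((c - mrgc_positions[n]) ** 2))
                else:
                    mu_n = sums[n] / counts[n]
                    d_gain = (counts[n] / (counts[n] + 1)) * np.sum((c - mu_n) ** 2) \
                        - (counts[k] / (counts[k] - 1)) * np.sum((c - mu_k) ** 2)
                if d_gain < best_d - 1e-15:
                    best, best_d = n, d_gain
            if best >= 0:
                members[k].remove(far)
                members[best].append(far)
                assign[far] = best
                counts[k] -= 1
                counts[best] += 1
                sums[k] -= c
                sums[best] += c
                moved = True
        if not moved:
            break
    return assign


# ---------------------------------------------------------------------------
# stage 2B


def center_members(conn: CenterConnectivity) -> list[np.ndarray]:
    """Cone indices per center (weights > 0)."""
    w = conn.weights.tocsc()
    return [w.indices[w.indptr[k]:w.indptr[k + 1]] for k in range(conn.n_cells)]


def center_purity(conn: CenterConnectivity, cone_mosaic: ConeMosaic) -> np.ndarray:
    """Majority-cone-type fraction per center."""
    out = np.empty(conn.n_cells)
    for k, mem in enumerate(center_members(conn)):
        t = cone_mosaic.types[mem]
        n_l = np.sum(t == 0)
        out[k] = max(n_l, len(t) - n_l) / max(len(t), 1)
    return out


def center_spread(conn: CenterConnectivity, cone_mosaic: ConeMosaic) -> np.ndarray:
    """Mean squared cone distance to the center centroid over local spacing^2."""
    out = np.empty(conn.n_cells)
    for k, mem in enumerate(center_members(conn)):
        xy = cone_mosaic.positions[mem]
        mu = xy.mean(axis=0)
        s2 = np.mean(cone_mosaic.spacing[mem]) ** 2
        out[k] = np.mean(np.sum((xy - mu) ** 2, axis=1)) / s2
    return out


def _objective(conn, cone_mosaic, phi):
    return (phi * -float(np.mean(center_spread(conn, cone_mosaic)))
            + (1.0 - phi) * float(np.mean(center_purity(conn, cone_mosaic))))


def refine_tradeoff(conn: CenterConnectivity, cone_mosaic: ConeMosaic,
                    mrgc_positions: np.ndarray, phi: float,
                    max_passes: int = 20) -> CenterConnectivity:
    """Stage 2B: greedy cone swaps between neighboring centers improving
    J = phi * (-spread) + (1 - phi) * purity. The partition invariants are
    preserved; J is non-decreasing over passes."""
    if conn.stage != "2A":
        raise ValueError("refine_tradeoff expects a stage-2A connectivity")
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    assign = conn.assignment()
    lm = np.flatnonzero(assign >= 0)
    mrgc_positions = np.asarray(mrgc_positions, dtype=float)
    pairs = _neighbor_pairs(mrgc_positions)
    types = cone_mosaic.types
    xy = cone_mosaic.positions
    sp = cone_mosaic.spacing

    def cell_terms(mem):
        if len(mem) == 0:
            return 0.0, 1.0
        p = xy[mem]
        mu = p.mean(axis=0)
        s2 = np.mean(sp[mem]) ** 2
        spread = np.mean(np.sum((p - mu) ** 2, axis=1)) / s2
        t = types[mem]
        n_l = np.sum(t == 0)
        purity = max(n_l, len(t) - n_l) / len(t)
        return spread, purity

    members = [list(np.flatnonzero(assign == k)) for k in range(len(mrgc_positions))]
    terms = [cell_terms(m) for m in members]
    n_cells = len(members)
    for _ in range(max_passes):
        improved = False
        for a, b in pairs:
            ma, mb = members[a], members[b]
            if len(ma) < 1 or len(mb) < 1:
                continue
            base = (phi * -(terms[a][0] + terms[b][0])
                    + (1 - phi) * (terms[a][1] + terms[b][1]))
            best = None
            for ia in ma:
                for ib in mb:
                    if types[ia] == types[ib]:
                        continue
                    na = [ib if m == ia else m for m in ma]
                    nb = [ia if m == ib else m for m in mb]
                    ta, tb = cell_terms(na), cell_terms(nb)
                    val = (phi * -(ta[0] + tb[0]) + (1 - phi) * (ta[1] + tb[1]))
                    if val > base + 1e-12 and (best is None or val > best[0]):
                        best = (val, ia, ib, na, nb, ta, tb)
            if best is not None:
                _, ia, ib, na, nb, ta, tb = best
                members[a], members[b] = na, nb
                terms[a], terms[b] = ta, tb
                assign[ia], assign[ib] = b, a
                improved = True
        if not improved:
            break
    w = sparse.csr_matrix((np.ones(len(lm)), (lm, assign[lm])),
                          shape=(len(cone_mosaic), n_cells))
    return CenterConnectivity(w, "2B", phi)


# ---------------------------------------------------------------------------
# stage 2C


def apply_divergence(conn: CenterConnectivity, cone_mosaic: ConeMosaic,
                     mrgc_positions: np.ndarray,
                     schedule: ExponentSchedule | None = None,
                     prune_below: float = 1e-3,
                     extent_factor: float = 1.19,
                     min_sigma_spacing: float = 0.4) -> CenterConnectivity:
    """Stage 2C: replace binary weights with supra-Gaussian radial profiles.

    sigma_k scales with the stage-2B center extent: ``extent_factor`` times
    the largest member distance from the centroid, floored at
    ``min_sigma_spacing`` cone spacings (the floor serves single-cone
    centers). At exponent 10 the profile passes 0.99 at 0.84 sigma and 0.01
    at 1.23 sigma, so this choice keeps the farthest member on the flat top
    while foreign cones of compact neighboring centers stay below 0.01; at
    exponent 2 the same sigma produces Gaussian overlap with neighbors.
    Weights are not renormalized (the response rule divides by the summed
    center weight).
    """
    if conn.stage != "2B":
        raise ValueError("apply_divergence expects a stage-2B connectivity")
    schedule = schedule or ExponentSchedule()
    mrgc_positions = np.asarray(mrgc_positions, dtype=float)
    xy = cone_mosaic.positions
    lm_mask = cone_mosaic.types != S
    tree = cKDTree(xy)
    rows, cols, vals = [], [], []
    mems = center_members(conn)
    for k, mem in enumerate(mems):
        p = xy[mem]
        mu = p.mean(axis=0)
        sigma = max(extent_factor * float(np.max(np.linalg.norm(p - mu, axis=1))),
                    min_sigma_spacing * float(np.mean(cone_mosaic.spacing[mem])))
        alpha = float(schedule(np.hypot(*mrgc_positions[k])))
        r_cut = sigma * (2.0 * np.log(1.0 / prune_below)) ** (1.0 / alpha)
        cand = tree.query_ball_point(mu, r=r_cut)
        cand = np.asarray([c for c in cand if lm_mask[c]], dtype=int)
        if len(cand) == 0:
            cand = np.asarray(mem)
        r = np.linalg.norm(xy[cand] - mu, axis=1)
        w = np.exp(-0.5 * (r / sigma) ** alpha)
        keep = w >= prune_below
        rows.extend(cand[keep])
        cols.extend([k] * int(keep.sum()))
        vals.extend(w[keep])
    w = sparse.csr_matrix((vals, (rows, cols)),
                          shape=(len(cone_mosaic), conn.n_cells))
    return CenterConnectivity(w, "2C", conn.phi)


def overlap_stats(conn: CenterConnectivity, weight_threshold: float = 0.1) -> dict:
    """Divergence summary: per-cone second-largest weight and sharing fraction."""
    w = conn.weights.tocsr()
    second = np.zeros(conn.n_cones)
    n_strong = np.zeros(conn.n_cones, dtype=int)
    for i in range(conn.n_cones):
        d = w.data[w.indptr[i]:w.indptr[i + 1]]
        if len(d) >= 2:
            second[i] = np.sort(d)[-2]
        n_strong[i] = int(np.sum(d >= weight_threshold))
    connected = np.asarray((w > 0).sum(axis=1)).ravel() > 0
    frac = float(np.mean(n_strong[connected] >= 2)) if connected.any() else 0.0
    return {
        "max_second_weight": float(second.max(initial=0.0)),
        "shared_fraction": frac,
        "second_weights": second,
    }
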