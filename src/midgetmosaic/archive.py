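"""Lossless mosaic serialization with config hashing.

Archives are NumPy ``.npz`` files holding float64 position/weight arrays,
integer type codes, sparse connectivity in coordinate-triplet form, and a
JSON metadata string embedding a SHA-256 hash of the configuration that
produced the mosaic. Loading verifies the format version and the hash, and
round trips are bit-exact.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
from scipy import sparse

from .lattice import ConeMosaic, PositionLattice
from .pipeline import Mosaic
from .wiring.center import CenterConnectivity

__all__ = ["save_mosaic", "load_mosaic", "config_hash"]

FORMAT_VERSION = 1


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()


def _sparse_triplets(m):
    coo = sparse.coo_matrix(m)
    return coo.row.astype(np.int64), coo.col.astype(np.int64), coo.data.astype(np.float64)


def save_mosaic(mosaic: Mosaic, path) -> None:
    cm = mosaic.cone_mosaic
    meta = {
        "format_version": FORMAT_VERSION,
        "stage": mosaic.stage,
        "config": mosaic.config,
        "config_hash": config_hash(mosaic.config),
        "seed": cm.lattice.seed,
        "region": list(cm.lattice.region),
    }
    arrays = {
        "cone_positions": cm.positions.astype(np.float64),
        "cone_types": cm.types.astype(np.int64),
        "cone_aperture": cm.aperture_diameter.astype(np.float64),
        "cone_spacing": cm.spacing.astype(np.float64),
        "mrgc_positions": mosaic.mrgc_positions.astype(np.float64),
        "meta_json": np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8),
    }
    if mosaic.conn_center is not None:
        r, c, v = _sparse_triplets(mosaic.conn_center.weights)
        arrays.update(pc_row=r, pc_col=c, pc_val=v,
                      pc_stage=np.frombuffer(mosaic.conn_center.stage.encode(), dtype=np.uint8),
                      pc_phi=np.array([np.nan if mosaic.conn_center.phi is None
                                       else mosaic.conn_center.phi]))
    if mosaic.P_surround is not None:
        r, c, v = _sparse_triplets(mosaic.P_surround)
        arrays.update(ps_row=r, ps_col=c, ps_val=v)
    if mosaic.jitter_multipliers is not None:
        arrays["jitter"] = mosaic.jitter_multipliers.astype(np.float64)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_mosaic(path) -> Mosaic:
    try:
        with np.load(path) as z:
            data = {k: z[k] for k in z.files}
    except Exception as e:  # noqa: BLE001 - surface any corruption uniformly
        raise ValueError(f"corrupt or unreadable mosaic archive: {e}") from e
    if "meta_json" not in data:
        raise ValueError("corrupt mosaic archive: missing metadata")
    meta = json.loads(bytes(data["meta_json"]).decode())
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported archive version {meta.get('format_version')}")
    if config_hash(meta["config"]) != meta["config_hash"]:
        raise ValueError("config hash mismatch: archive metadata was altered")
    lat = PositionLattice(data["cone_positions"], "cone", int(meta["seed"]), 0,
                          tuple(meta["region"]))
    cm = ConeMosaic(lat, data["cone_types"], data["cone_aperture"], data["cone_spacing"])
    mosaic = Mosaic(cm, data["mrgc_positions"], stage=meta["stage"], config=meta["config"])
    n_cones = len(cm.types)
    n_cells = len(mosaic.mrgc_positions)
    if "pc_row" in data:
        w = sparse.csr_matrix((data["pc_val"], (data["pc_row"], data["pc_col"])),
                              shape=(n_cones, n_cells))
        phi = float(data["pc_phi"][0])
        mosaic.conn_center = CenterConnectivity(
            w, bytes(data["pc_stage"]).decode(), None if np.isnan(phi) else phi)
    if "ps_row" in data:
        mosaic.P_surround = sparse.csr_matrix(
            (data["ps_val"], (data["ps_row"], data["ps_col"])), shape=(n_cones, n_cells))
    if "jitter" in data:
        mosaic.jitter_multipliers = data["jitter"]
    return mosaic
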