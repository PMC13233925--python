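"""Eccentricity and coordinate conversions.

All spatial quantities in this package live in visual-field degrees of a right
eye, with the origin at the foveal center and x > 0 pointing temporally.
Conversions to linear retinal eccentricity (mm) use a cubic schematic-eye
polynomial for the human eye; macaque angular eccentricity is obtained by
equating linear eccentricity across species and applying a constant retinal
magnification factor for the macaque eye.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

__all__ = [
    "deg_to_mm_human",
    "mm_to_deg_human",
    "mm_per_deg_human",
    "human_deg_to_macaque_deg",
    "MACAQUE_MM_PER_DEG",
]


def _load_params() -> dict:
    with resources.files("midgetmosaic.data").joinpath("density_params.json").open() as fh:
        return json.load(fh)


_PARAMS = _load_params()
_C1 = _PARAMS["deg_to_mm_human"]["c1"]
_C2 = _PARAMS["deg_to_mm_human"]["c2"]
_C3 = _PARAMS["deg_to_mm_human"]["c3"]
MACAQUE_MM_PER_DEG = _PARAMS["macaque_mm_per_deg"]


def _check_nonneg(ecc, name: str):
    arr = np.asarray(ecc, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative, got {arr.min()}")
    return arr


def deg_to_mm_human(ecc_deg):
    """Convert angular eccentricity (deg) to linear eccentricity on the human retina (mm)."""
    r = _check_nonneg(ecc_deg, "ecc_deg")
    return _C1 * r + _C2 * r**2 + _C3 * r**3


def mm_per_deg_human(ecc_deg):
    """Local retinal magnification d(mm)/d(deg) at a given angular eccentricity."""
    r = _check_nonneg(ecc_deg, "ecc_deg")
    return _C1 + 2.0 * _C2 * r + 3.0 * _C3 * r**2


def mm_to_deg_human(ecc_mm):
    """Invert the cubic deg->mm map by Newton iteration (exact round trip)."""
    mm = _check_nonneg(ecc_mm, "ecc_mm")
    scalar = mm.ndim == 0
    mm = np.atleast_1d(mm)
    deg = mm / _C1  # good initial guess: the map is nearly linear
    for _ in range(60):
        f = _C1 * deg + _C2 * deg**2 + _C3 * deg**3 - mm
        fp = _C1 + 2.0 * _C2 * deg + 3.0 * _C3 * deg**2
        step = f / fp
        deg = deg - step
        if np.all(np.abs(step) < 1e-13 * np.maximum(1.0, np.abs(deg))):
            break
    deg = np.where(mm == 0.0, 0.0, deg)
    return float(deg[0]) if scalar else deg


def human_deg_to_macaque_deg(ecc_deg):
    """Equivalent macaque angular eccentricity for a human angular eccentricity.

    Human degrees are first mapped to retinal mm; macaque and human linear
    eccentricities are assumed identical; the macaque angle follows from a
    constant magnification factor of 0.221 mm/deg.
    """
    return deg_to_mm_human(ecc_deg) / MACAQUE_MM_PER_DEG
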