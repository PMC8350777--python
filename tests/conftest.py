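"""Shared fixtures: small phantoms and pre-solved deformation fields.

The expensive objects (solved fields, the scaled-down paired experiment) are
session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

import corticosim as cs
from corticosim import toycortex


def small_grid(n: int = 40, spacing: float = 1.0) -> cs.Volume:
    """Empty n^3 grid with 1 mm voxels and the world origin at its centre."""
    aff = np.eye(4)
    aff[:3, :3] *= spacing
    aff[:3, 3] = -spacing * (n - 1) / 2.0
    return cs.Volume(np.zeros((n, n, n)), aff)


SMALL_SPEC = cs.PhantomSpec(
    grid_shape=(40, 40, 40), r_wm_mm=9.0, thickness_mm=3.0, noise_sd=0.0, seed=7
)
# 6 mm cubic ROI centred on the mid-surface (radius 10.5 mm) of SMALL_SPEC
SMALL_ROI = cs.ROISpec(
    corner_world=(7.5, -3.0, -3.0), size_mm=6.0, contraction_volume=0.2, pad_mm=4.0
)


@pytest.fixture(scope="session")
def noiseless_phantom():
    return cs.make_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def solved_field(noiseless_phantom):
    """Deformation field for SMALL_ROI at 20% volume contraction."""
    grid = noiseless_phantom.volume
    roi_mask = cs.make_roi_mask(SMALL_ROI, grid)
    ring = cs.make_tolerance_mask(roi_mask, SMALL_ROI.pad_mm, grid)
    free = grid.like(np.asarray(roi_mask.data, bool) | np.asarray(ring.data, bool))
    det = cs.make_determinant_map(roi_mask, SMALL_ROI.contraction_volume, grid)
    field = cs.solve_deformation_field(det, free)
    return {"field": field, "roi_mask": roi_mask, "free": free, "det": det}


def measure_thickness(subject, mesh=None, metric: str = "tlink_ray") -> np.ndarray:
    """Classify a subject's intensity volume and estimate per-vertex thickness."""
    mesh = mesh if mesh is not None else subject.mid_surface
    means = dict(zip(("csf", "gm", "wm"), subject.spec.intensity_means))
    cls = toycortex.classify_tissues(subject.volume, means)
    res = toycortex.estimate_thickness(
        cls.class_maps, mesh, max_search_mm=4.0 * subject.spec.thickness_mm
    )
    return res.thickness.values
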