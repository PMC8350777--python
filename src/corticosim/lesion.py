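"""Simulated focal lesions via Jacobian-determinant-constrained warps.

A lesion is specified as a region of interest (cube or inscribed ellipsoid,
anchored by the top/left/back corner of its bounding box in world mm) plus a
volume contraction ratio.  The simulation pipeline is:

1. build a target determinant map — ``1 - contraction`` inside the ROI,
   ``1`` elsewhere;
2. build a tolerance ring by dilating the ROI by ``pad_mm``; displacement is
   allowed only on ROI ∪ ring (the *free region*) so the compensating warp is
   absorbed there and the rest of the image is untouched, exactly;
3. solve iteratively for a displacement field ``u`` whose warp
   ``phi: x -> x + u(x)`` attains the target determinant inside the ROI;
4. resample the image through the *inverse* of ``phi``, so that tissue inside
   the ROI genuinely shrinks by the requested factor (a determinant below one
   is a volume loss of the anatomy, as in deformation-based morphometry).

The solver is damped gradient descent on

    L(u) = sum_ROI (det(I + grad u) - target)^2 + lambda * sum |grad u|^2

with the displacement clamped to zero outside the free region after every
step and a backtracking line search that keeps the logged ROI determinant
error non-increasing.  Only the ROI carries the data term: the ring must be
free to take up the displaced volume (a warp that is identity on the ring
boundary cannot satisfy ``det = 1`` throughout the ring while removing
volume from the ROI), so the ring is shaped by the smoothness penalty alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import Volume

__all__ = [
    "ROISpec",
    "DeformationField",
    "linear_from_volume_contraction",
    "volume_from_linear_contraction",
    "detectable_change_mm",
    "make_roi_mask",
    "make_tolerance_mask",
    "make_determinant_map",
    "solve_deformation_field",
    "invert_displacement",
    "jacobian_determinant",
    "apply_deformation",
    "verify_locality",
    "simulate_lesion",
]


# ---------------------------------------------------------------------------
# contraction algebra
# ---------------------------------------------------------------------------

def linear_from_volume_contraction(r_vol: float) -> float:
    """Per-axis contraction realising an isotropic volume contraction.

    ``1 - (1 - r_vol)**(1/3)``: a 20% volume loss is a 7.17% loss along each
    dimension.  Negative ratios (expansion) are allowed.
    """
    if r_vol >= 1:
        raise ValueError("volume contraction ratio must be < 1")
    return 1.0 - (1.0 - r_vol) ** (1.0 / 3.0)


def volume_from_linear_contraction(r_lin: float) -> float:
    """Inverse of :func:`linear_from_volume_contraction`."""
    if r_lin >= 1:
        raise ValueError("linear contraction ratio must be < 1")
    return 1.0 - (1.0 - r_lin) ** 3


def detectable_change_mm(linear_ratio: float, roi_size_mm: float) -> float:
    """Absolute thickness change implied by a per-axis ratio over an ROI size.

    E.g. a 7% per-dimension contraction of a 5 mm ROI is a 0.35 mm change —
    the scale on which detection thresholds are quoted.
    """
    return linear_ratio * roi_size_mm


# ---------------------------------------------------------------------------
# ROI masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROISpec:
    """A lesion region: shape, bounding-box corner, size, contraction, pad.

    ``corner_world`` anchors the low corner (top/left/back) of the bounding
    box; the box extends by ``size_mm`` along each axis and the deformation
    is centred on ``corner + size/2``.  ``contraction_volume`` is the volume
    fraction removed (negative expands).  ``pad_mm`` is the tolerance-ring
    width.
    """

    corner_world: tuple[float, float, float]
    size_mm: float | tuple[float, float, float] = 10.0
    shape: str = "cube"
    contraction_volume: float = 0.2
    pad_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.shape not in ("cube", "ellipsoid"):
            raise ValueError("shape must be 'cube' or 'ellipsoid'")
        if np.any(np.asarray(self.size_vector) <= 0):
            raise ValueError("size_mm must be positive")
        if self.contraction_volume >= 1:
            raise ValueError("contraction_volume must be < 1")
        if self.pad_mm < 0:
            raise ValueError("pad_mm must be non-negative")

    @property
    def size_vector(self) -> np.ndarray:
        s = np.asarray(self.size_mm, dtype=float)
        return np.full(3, float(s)) if s.ndim == 0 else s

    @property
    def center_world(self) -> np.ndarray:
        """Deformation centre: the centre of the bounding box."""
        return np.asarray(self.corner_world, dtype=float) + self.size_vector / 2.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorised point-in-ROI test for (..., 3) world-mm points.

        Cube membership is half-open, ``corner <= p < corner + size`` per
        axis; the ellipsoid is the one inscribed in that box.
        """
        p = np.asarray(points, dtype=float)
        corner = np.asarray(self.corner_world, dtype=float)
        size = self.size_vector
        if self.shape == "cube":
            return np.all((p >= corner) & (p < corner + size), axis=-1)
        rel = (p - (corner + size / 2.0)) / (size / 2.0)
        return np.sum(rel**2, axis=-1) <= 1.0


def make_roi_mask(spec: ROISpec, grid: Volume) -> Volume:
    """Boolean mask of voxels whose center lies inside the ROI solid."""
    corner = np.asarray(spec.corner_world, dtype=float)
    hi = corner + spec.size_vector
    centers = grid.voxel_center_grid()
    lo_w = grid.voxel_to_world(np.zeros(3))
    hi_w = grid.voxel_to_world(np.asarray(grid.shape) - 1.0)
    gmin, gmax = np.minimum(lo_w, hi_w), np.maximum(lo_w, hi_w)
    if np.any(corner < gmin - 1e-9) or np.any(hi > gmax + 1e-9):
        raise ValueError(
            f"ROI box [{corner}, {hi}] extends outside the grid [{gmin}, {gmax}]"
        )
    return grid.like(spec.contains(centers))


def make_tolerance_mask(roi_mask: Volume, pad_mm: float, grid: Volume | None = None) -> Volume:
    """Tolerance ring: ROI dilated by ``pad_mm``, minus the ROI itself.

    Dilation is iterative 26-connected, one voxel (per-axis spacing) at a
    time, ``ceil(pad_mm / spacing)`` times per axis.  The free region where
    the solver may move tissue is ``roi | ring``.
    """
    grid = grid or roi_mask
    spacing = grid.spacing
    if pad_mm < np.min(spacing):
        raise ValueError(f"pad_mm must be at least one voxel ({np.min(spacing)} mm)")
    n_iter = int(np.ceil(pad_mm / float(np.min(spacing)) - 1e-9))
    struct = np.ones((3, 3, 3), dtype=bool)  # 26-connected: one voxel per axis per pass
    dilated = ndimage.binary_dilation(np.asarray(roi_mask.data, dtype=bool),
                                      structure=struct, iterations=n_iter)
    if dilated[0, :, :].any() or dilated[-1, :, :].any() or dilated[:, 0, :].any() \
            or dilated[:, -1, :].any() or dilated[:, :, 0].any() or dilated[:, :, -1].any():
        raise ValueError("tolerance ring reaches the grid border; enlarge the grid")
    ring = dilated & ~np.asarray(roi_mask.data, dtype=bool)
    return grid.like(ring)


def make_determinant_map(roi_mask: Volume, contraction_volume: float, grid: Volume | None = None) -> Volume:
    """Target Jacobian determinant: ``1 - contraction`` in the ROI, 1 outside."""
    if contraction_volume >= 1:
        raise ValueError("contraction_volume must be < 1")
    grid = grid or roi_mask
    det = np.ones(roi_mask.shape, dtype=np.float64)
    det[np.asarray(roi_mask.data, dtype=bool)] = 1.0 - contraction_volume
    return grid.like(det)


# ---------------------------------------------------------------------------
# deformation field
# ---------------------------------------------------------------------------

@dataclass
class DeformationField:
    """Displacement of the forward warp ``phi: x -> x + u(x)`` in world mm.

    ``displacement`` has shape (3, *grid); it is exactly zero outside
    ``free_mask``.  ``solver_log`` records the mean absolute ROI determinant
    error per accepted iteration.
    """

    displacement: np.ndarray
    grid: Volume
    free_mask: Volume
    solver_log: list[float] = field(default_factory=list)
    converged: bool = True

    def magnitude(self) -> Volume:
        return self.grid.like(np.linalg.norm(self.displacement, axis=0))


def _grad(arr: np.ndarray, spacing: np.ndarray) -> list[np.ndarray]:
    """Spacing-aware central differences, one-sided at grid borders."""
    return list(np.gradient(arr, *spacing, edge_order=1))


def _det3(g: list[list[np.ndarray]]) -> np.ndarray:
    """det(I + G) for G[i][j] arrays."""
    a = 1.0 + g[0][0]
    b, c = g[0][1], g[0][2]
    d, e = g[1][0], 1.0 + g[1][1]
    f = g[1][2]
    h, i_ = g[2][0], g[2][1]
    j = 1.0 + g[2][2]
    return a * (e * j - f * i_) - b * (d * j - f * h) + c * (d * i_ - e * h)


def _cofactors(g: list[list[np.ndarray]]) -> list[list[np.ndarray]]:
    """Cofactor matrix C with C[i][j] = d det(J)/d J[i][j], J = I + G."""
    a = 1.0 + g[0][0]
    b, c = g[0][1], g[0][2]
    d, e = g[1][0], 1.0 + g[1][1]
    f = g[1][2]
    h, i_ = g[2][0], g[2][1]
    j = 1.0 + g[2][2]
    return [
        [e * j - f * i_, -(d * j - f * h), d * i_ - e * h],
        [-(b * j - c * i_), a * j - c * h, -(a * i_ - b * h)],
        [b * f - c * e, -(a * f - c * d), a * e - b * d],
    ]


def _laplacian(arr: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    out = np.zeros_like(arr)
    for ax in range(3):
        plus = np.concatenate([np.take(arr, range(1, arr.shape[ax]), axis=ax),
                               np.take(arr, [-1], axis=ax)], axis=ax)
        minus = np.concatenate([np.take(arr, [0], axis=ax),
                                np.take(arr, range(0, arr.shape[ax] - 1), axis=ax)], axis=ax)
        out += (plus + minus - 2 * arr) / spacing[ax] ** 2
    return out


def jacobian_determinant(field: DeformationField | np.ndarray, grid: Volume | None = None) -> Volume:
    """Determinant of ``x -> x + u(x)`` by spacing-aware central differences.

    The verification companion of the solver: it is computed from the stored
    field alone and never from the solver's internal state.
    """
    if isinstance(field, DeformationField):
        u, grid = field.displacement, field.grid
    else:
        u = field
        if grid is None:
            raise ValueError("grid required when passing a raw displacement array")
    spacing = grid.spacing
    g = [_grad(u[i], spacing) for i in range(3)]
    return grid.like(_det3(g))


def solve_deformation_field(
    det_map: Volume,
    free_mask: Volume,
    max_iter: int = 500,
    step: float = 0.1,
    smooth_lambda: float = 0.01,
    tol: float = 0.01,
) -> DeformationField:
    """Iteratively fit a displacement field to a target determinant map.

    Damped gradient descent with a backtracking line search; the logged
    per-iteration mean absolute determinant error over the ROI (the non-unit
    region of ``det_map``) is non-increasing by construction.  Displacement
    is hard-clamped to zero outside ``free_mask`` after every step, and any
    step that would make the determinant non-positive anywhere is rejected.

    Raises ``RuntimeError`` on a determinant sign flip that backtracking
    cannot avoid; warns (with the log attached) if ``tol`` is not reached in
    ``max_iter`` iterations.
    """
    target = np.asarray(det_map.data, dtype=np.float64)
    if np.any(target <= 0):
        raise ValueError("target determinant must be strictly positive")
    free = np.asarray(free_mask.data, dtype=bool)
    roi = free & (target != 1.0)
    if np.any((target != 1.0) & ~free):
        raise ValueError("free_mask must contain the non-unit region of det_map")

    spacing = det_map.spacing
    u = np.zeros((3,) + det_map.shape, dtype=np.float64)

    if not roi.any() or np.allclose(target, 1.0):
        return DeformationField(u, det_map, free_mask, solver_log=[0.0], converged=True)

    def roi_error(uu: np.ndarray) -> float:
        g = [_grad(uu[i], spacing) for i in range(3)]
        return float(np.abs(_det3(g)[roi] - target[roi]).mean())

    log: list[float] = []
    err = roi_error(u)
    log.append(err)
    s = step
    converged = err <= tol
    it = 0
    while err > tol and it < max_iter:
        it += 1
        g = [_grad(u[i], spacing) for i in range(3)]
        det = _det3(g)
        cof = _cofactors(g)
        resid = np.where(roi, 2.0 * (det - target), 0.0)
        grad_u = np.empty_like(u)
        for i in range(3):
            div = np.zeros(det_map.shape)
            for j in range(3):
                div += np.gradient(resid * cof[i][j], spacing[j], axis=j, edge_order=1)
            grad_u[i] = -div - 2.0 * smooth_lambda * _laplacian(u[i], spacing)

        accepted = False
        s *= 2.0  # let the line search grow; backtracking below reins it in
        for _ in range(20):
            u_new = u - s * grad_u
            u_new[:, ~free] = 0.0
            gn = [_grad(u_new[i], spacing) for i in range(3)]
            det_new = _det3(gn)
            if det_new.min() <= 0:
                s *= 0.5
                continue
            e_new = float(np.abs(det_new[roi] - target[roi]).mean())
            if e_new <= err:
                u, err = u_new, e_new
                accepted = True
                break
            s *= 0.5
        log.append(err)
        if not accepted:
            break  # plateau: no descent direction at any tried step
        if err <= tol:
            converged = True
            break

    converged = err <= tol
    if not converged:
        warnings.warn(
            f"deformation solver stopped at ROI determinant error {err:.4g} "
            f"(tol {tol}) after {it} iterations",
            stacklevel=2,
        )
    final = jacobian_determinant(u, det_map)
    if final.data.min() <= 0:
        raise RuntimeError("solved field has a non-positive Jacobian determinant")
    return DeformationField(u, det_map, free_mask, solver_log=log, converged=converged)


def invert_displacement(field: DeformationField, n_iter: int = 20, tol_mm: float = 1e-4) -> np.ndarray:
    """Displacement ``v`` of the inverse warp, ``phi^{-1}(y) = y + v(y)``.

    Fixed-point iteration ``v <- -u(y + v(y))`` with trilinear sampling of
    ``u``.  Because the forward warp is the identity outside the free region
    (and maps the free region onto itself), ``v`` is exactly zero there.
    """
    u = field.displacement
    spacing = field.grid.spacing
    base = np.stack(np.meshgrid(*[np.arange(n) for n in field.grid.shape], indexing="ij"), axis=0).astype(float)
    v = np.zeros_like(u)
    for _ in range(n_iter):
        coords = base + v / spacing[:, None, None, None]
        v_new = np.empty_like(v)
        for i in range(3):
            v_new[i] = -ndimage.map_coordinates(u[i], coords, order=1, mode="nearest")
        delta = np.max(np.abs(v_new - v))
        v = v_new
        if delta < tol_mm:
            break
    free = np.asarray(field.free_mask.data, dtype=bool)
    v[:, ~free] = 0.0  # phi is the identity there, hence so is its inverse
    return v


def apply_deformation(volume: Volume, field: DeformationField, interpolation: str = "trilinear") -> Volume:
    """Warp ``volume`` through the field's forward map.

    Resamples through the inverse warp, ``out(y) = in(phi^{-1}(y))``, so a
    target determinant below one shrinks the anatomy inside the ROI by that
    volume factor.  Outside the free region the output equals the input
    bit-for-bit (the sample point is the voxel's own center).  Out-of-grid
    samples replicate the border value.
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError("interpolation must be 'trilinear' or 'nearest'")
    if volume.shape != field.grid.shape or not np.allclose(volume.affine, field.grid.affine, atol=1e-6):
        raise ValueError("volume and deformation field are on different grids")
    order = 1 if interpolation == "trilinear" else 0
    if not np.any(field.displacement):
        return volume.like(np.asarray(volume.data).copy())
    v = invert_displacement(field)
    spacing = volume.spacing
    base = np.stack(np.meshgrid(*[np.arange(n) for n in volume.shape], indexing="ij"), axis=0).astype(float)
    coords = base + v / spacing[:, None, None, None]
    data = np.asarray(volume.data, dtype=np.float64)
    out = ndimage.map_coordinates(data, coords, order=order, mode="nearest")
    free = np.asarray(field.free_mask.data, dtype=bool)
    out[~free] = data[~free]  # exact identity where displacement is zero
    return volume.like(out)


def verify_locality(
    original: Volume,
    deformed: Volume,
    free_mask: Volume,
    class_maps_original: dict[str, Volume] | None = None,
    class_maps_deformed: dict[str, Volume] | None = None,
    roi_mask: Volume | None = None,
):
    """Check that only the free region changed; optionally tabulate tissue shifts.

    Returns ``(max_abs_outside, table)`` where ``max_abs_outside`` is the
    largest absolute intensity change outside ``free_mask`` (zero for fields
    produced by this package) and ``table`` is a per-class DataFrame of mean
    probability changes inside/outside ``roi_mask`` in percentage points
    (``None`` when class maps are not supplied).
    """
    import pandas as pd

    if original.shape != deformed.shape:
        raise ValueError("volumes are on different grids")
    outside = ~np.asarray(free_mask.data, dtype=bool)
    delta = np.abs(np.asarray(deformed.data) - np.asarray(original.data))
    max_abs = float(delta[outside].max()) if outside.any() else 0.0

    table = None
    if class_maps_original is not None and class_maps_deformed is not None:
        mask = np.asarray((roi_mask or free_mask).data, dtype=bool)
        rows = []
        for cname in class_maps_original:
            before = np.asarray(class_maps_original[cname].data, dtype=float)
            after = np.asarray(class_maps_deformed[cname].data, dtype=float)
            rows.append(
                {
                    "class": cname,
                    "inside_pp": 100.0 * float(after[mask].mean() - before[mask].mean()),
                    "outside_pp": 100.0 * float(after[~mask].mean() - before[~mask].mean()),
                }
            )
        table = pd.DataFrame(rows)
    return max_abs, table


def simulate_lesion(
    volume: Volume,
    roi: ROISpec,
    max_iter: int = 500,
    step: float = 0.1,
    smooth_lambda: float = 0.01,
    tol: float = 0.01,
    field: DeformationField | None = None,
) -> tuple[Volume, DeformationField]:
    """Convenience wrapper: ROI -> determinant map -> solve -> apply.

    Pass a precomputed ``field`` to reuse one solve across many subjects that
    share a grid (the field depends only on the ROI, not on the image).
    """
    if field is None:
        roi_mask = make_roi_mask(roi, volume)
        ring = make_tolerance_mask(roi_mask, roi.pad_mm, volume)
        free = volume.like(np.asarray(roi_mask.data, bool) | np.asarray(ring.data, bool))
        det = make_determinant_map(roi_mask, roi.contraction_volume, volume)
        field = solve_deformation_field(det, free, max_iter=max_iter, step=step,
                                        smooth_lambda=smooth_lambda, tol=tol)
    return apply_deformation(volume, field), field
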