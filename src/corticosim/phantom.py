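"""Digital brain phantoms with an analytically known cortical ribbon.

The phantom is a spherical-shell brain: a white-matter ball of radius
``r_wm_mm``, a grey-matter ribbon of uniform thickness ``thickness_mm`` on
top of it, and CSF outside.  The geometry is deliberately simple so that the
true cortical thickness, surface normals and tissue boundaries are known in
closed form; a lesion simulated inside the ribbon can then be scored against
exact ground truth rather than against another pipeline's output.

Tissue class probabilities ramp linearly over one voxel across each
interface, so partial-volume mixing — the effect that limits boundary
localisation on real scans — is present and controllable.  Intensities are
the probability-weighted class means plus i.i.d. Gaussian noise.

Two cohort constructors emulate the study designs the toolkit targets:
repeated scans of one anatomy (fresh noise, fixed geometry) and a
between-subject cohort (per-subject ribbon-thickness jitter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import SurfaceMesh, VertexScalars, Volume

__all__ = [
    "PhantomSpec",
    "PhantomSubject",
    "make_phantom",
    "make_repeated_scans",
    "make_cohort",
    "split_cohort",
]

CLASS_NAMES = ("csf", "gm", "wm")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one spherical-shell phantom.

    Defaults give a 52 mm cube of 1 mm isotropic voxels holding a 12 mm WM
    ball and a 3 mm GM ribbon (outer radius 15 mm), T1-like class means with
    equal 40-unit GM/WM and GM/CSF contrasts, and a noise SD of 5 — which
    propagates to a per-vertex thickness scan-rescan noise of roughly
    0.15-0.2 mm, the scale reported for real repeat scans.
    """

    grid_shape: tuple[int, int, int] = (52, 52, 52)
    spacing_mm: float = 1.0
    center_world: tuple[float, float, float] = (0.0, 0.0, 0.0)
    r_wm_mm: float = 12.0
    thickness_mm: float = 3.0
    intensity_means: tuple[float, float, float] = (30.0, 70.0, 110.0)  # CSF, GM, WM
    noise_sd: float = 5.0
    seed: int = 0
    subdivisions: int = 3  # icosphere refinement of the mid-surface (642 vertices)

    def __post_init__(self) -> None:
        if self.r_wm_mm <= 0 or self.thickness_mm <= 0:
            raise ValueError("r_wm_mm and thickness_mm must be positive")
        if len(set(self.intensity_means)) != 3:
            raise ValueError("class intensity means must be distinct")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        r_out = self.r_wm_mm + self.thickness_mm
        half_extent = min(self.grid_shape) * self.spacing_mm / 2.0
        if r_out + 2 * self.spacing_mm > half_extent:
            raise ValueError(
                f"outer radius {r_out} mm does not fit in the grid "
                f"(half extent {half_extent} mm) with a 2-voxel margin"
            )

    @property
    def affine(self) -> np.ndarray:
        """Axis-aligned affine centring the world origin offset on the grid."""
        a = np.eye(4)
        a[:3, :3] *= self.spacing_mm
        shape = np.asarray(self.grid_shape, dtype=float)
        a[:3, 3] = np.asarray(self.center_world) - self.spacing_mm * (shape - 1) / 2.0
        return a


@dataclass
class PhantomSubject:
    """One generated phantom: intensities, true class maps, true geometry."""

    volume: Volume
    class_maps: dict[str, Volume]
    mid_surface: SurfaceMesh
    true_thickness: VertexScalars
    spec: PhantomSpec = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def subject_spacing(self) -> np.ndarray:
        return self.volume.spacing


def _ramp(signed_distance: np.ndarray, width: float) -> np.ndarray:
    """Linear 0->1 ramp of the given width centred on the zero level set."""
    return np.clip(signed_distance / width + 0.5, 0.0, 1.0)


def _icosphere(radius: float, center: np.ndarray, subdivisions: int) -> SurfaceMesh:
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(tm.vertices) + center, np.asarray(tm.faces))


def make_phantom(spec: PhantomSpec) -> PhantomSubject:
    """Generate one phantom subject from ``spec`` (deterministic given seed).

    Class probabilities at each voxel come from the signed distance of its
    center to the WM sphere (radius ``r_wm_mm``) and to the pial sphere
    (radius ``r_wm_mm + thickness_mm``), with a one-voxel linear ramp across
    each interface; they sum to one everywhere.  The mid-surface is an
    icosphere at radius ``r_wm + thickness/2``.
    """
    if spec.thickness_mm < spec.spacing_mm:
        import warnings

        warnings.warn(
            "GM ribbon is thinner than one voxel; thickness estimates will be "
            "dominated by partial volume",
            stacklevel=2,
        )
    grid = Volume(np.zeros(spec.grid_shape, dtype=np.float64), spec.affine)
    xyz = grid.voxel_center_grid()
    r = np.linalg.norm(xyz - np.asarray(spec.center_world), axis=-1)

    width = spec.spacing_mm
    inside_wm = _ramp(spec.r_wm_mm - r, width)  # 1 deep inside WM
    inside_pial = _ramp(spec.r_wm_mm + spec.thickness_mm - r, width)  # 1 inside pial
    wm = inside_wm
    gm = inside_pial - inside_wm
    csf = 1.0 - inside_pial
    class_maps = {
        "csf": grid.like(csf),
        "gm": grid.like(gm),
        "wm": grid.like(wm),
    }

    means = dict(zip(CLASS_NAMES, spec.intensity_means))
    intensity = sum(class_maps[c].data * means[c] for c in CLASS_NAMES)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=intensity.shape)

    mid_r = spec.r_wm_mm + spec.thickness_mm / 2.0
    mesh = _icosphere(mid_r, np.asarray(spec.center_world, dtype=float), spec.subdivisions)
    true_t = mesh.attach(np.full(mesh.n_vertices, spec.thickness_mm), "thickness_mm")

    return PhantomSubject(
        volume=grid.like(intensity),
        class_maps=class_maps,
        mid_surface=mesh,
        true_thickness=true_t,
        spec=spec,
    )


def make_repeated_scans(spec: PhantomSpec, n_scans: int) -> list[PhantomSubject]:
    """Repeated scans of one anatomy: fixed geometry, fresh noise per scan.

    Scan ``i`` uses seed ``spec.seed + i``; geometry, class maps and the
    mid-surface are identical across scans.
    """
    if n_scans < 2:
        raise ValueError("n_scans must be >= 2")
    return [make_phantom(replace(spec, seed=spec.seed + i)) for i in range(n_scans)]


def make_cohort(
    spec: PhantomSpec, n_subjects: int, thickness_sd_mm: float = 0.5
) -> list[PhantomSubject]:
    """Between-subject cohort with ribbon-thickness jitter.

    Subject ``i`` draws its true thickness from
    ``Normal(spec.thickness_mm, thickness_sd_mm)`` truncated to stay positive
    (and at least a tenth of the mean), and uses seed ``spec.seed + i`` for
    its scan noise.  All subjects share the grid and sphere centre, so ROI
    world coordinates transfer across the cohort — the phantom analogue of a
    stereotaxically registered population.  The default 0.5 mm SD matches the
    between-subject spread of mean cortical thickness reported for healthy
    adult cohorts.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if thickness_sd_mm < 0:
        raise ValueError("thickness_sd_mm must be >= 0")
    rng = np.random.default_rng(spec.seed)
    lo = 0.1 * spec.thickness_mm
    subjects = []
    for i in range(n_subjects):
        t = float(rng.normal(spec.thickness_mm, thickness_sd_mm))
        while t <= lo:  # truncate: a non-positive ribbon is meaningless
            t = float(rng.normal(spec.thickness_mm, thickness_sd_mm))
        subjects.append(make_phantom(replace(spec, thickness_mm=t, seed=spec.seed + i)))
    return subjects


def split_cohort(n_subjects: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random split of ``range(n_subjects)`` into two halves.

    Returns (group1, group2) index arrays; group1 gets the extra subject when
    ``n_subjects`` is odd.  The split is reproducible from the seed alone.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_subjects)
    half = (n_subjects + 1) // 2
    return np.sort(order[:half]), np.sort(order[half:])
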