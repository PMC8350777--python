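"""Domain containers and file I/O for volumes, surfaces and per-vertex tables.

All spatial quantities are expressed in world millimetres in an RAS-like
frame.  A :class:`Volume` couples a 3-D scalar array with the 4x4 affine
mapping 0-based voxel indices ``(i, j, k, 1)`` to world coordinates, exactly
as NIfTI-1 defines it.  Surfaces are triangle meshes whose vertices live in
the same world frame, so region-of-interest coordinates transfer between
image and surface without further registration.

On-disk formats are deliberately minimal and diffable: NIfTI-1 for volumes,
ASCII OFF for meshes, and tab-separated text for per-vertex scalars, cohort
tables and detection reports.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "SurfaceMesh",
    "VertexScalars",
    "CohortTable",
    "read_volume",
    "write_volume",
    "read_mesh",
    "write_mesh",
    "read_vertex_table",
    "write_vertex_table",
    "write_report",
    "read_report",
]


@dataclass
class Volume:
    """A 3-D scalar grid with a voxel-to-world affine.

    Parameters
    ----------
    data
        3-D array of scalars (intensities, class probabilities or Jacobian
        determinants).
    affine
        4x4 invertible matrix; ``world = affine @ (i, j, k, 1)``.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size in mm along each axis (norm of the affine columns)."""
        s = np.linalg.norm(self.affine[:3, :3], axis=0)
        if np.any(s <= 0):
            raise ValueError("voxel spacing must be strictly positive")
        return s

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to (..., 3) world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm to continuous (..., 3) voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine[:3, :3])
        return (xyz - self.affine[:3, 3]) @ inv.T

    def voxel_center_grid(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (*grid, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return self.voxel_to_world(idx)

    def like(self, data: np.ndarray) -> "Volume":
        """A new Volume on the same grid carrying ``data``."""
        return Volume(data, self.affine.copy())


@dataclass
class SurfaceMesh:
    """Triangle mesh in world mm with a vertex adjacency table."""

    vertices: np.ndarray  # (N, 3) float, mm
    faces: np.ndarray  # (M, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("face indices out of range")
        self._neighbors: list[np.ndarray] | None = None
        self._vertex_normals: np.ndarray | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def neighbor_table(self) -> list[np.ndarray]:
        """Per-vertex sorted arrays of adjacent vertex indices (symmetric)."""
        if self._neighbors is None:
            sets: list[set[int]] = [set() for _ in range(self.n_vertices)]
            for a, b, c in self.faces:
                sets[a].update((b, c))
                sets[b].update((a, c))
                sets[c].update((a, b))
            self._neighbors = [np.array(sorted(s), dtype=int) for s in sets]
        return self._neighbors

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges, shape (E, 2) with col0 < col1."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [0, 2]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    @property
    def mean_edge_length_mm(self) -> float:
        e = self.edges
        return float(np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1).mean())

    @property
    def vertex_normals(self) -> np.ndarray:
        """Outward area-weighted vertex normals (consistent winding assumed)."""
        if self._vertex_normals is None:
            import trimesh

            tm = trimesh.Trimesh(self.vertices, self.faces, process=False)
            self._vertex_normals = np.asarray(tm.vertex_normals, dtype=float).copy()
        return self._vertex_normals

    def attach(self, values: np.ndarray, name: str) -> "VertexScalars":
        """Build VertexScalars, asserting alignment with this mesh."""
        vs = VertexScalars(np.asarray(values, dtype=float), name)
        if len(vs.values) != self.n_vertices:
            raise ValueError(
                f"vertex scalar length {len(vs.values)} does not match mesh "
                f"with {self.n_vertices} vertices"
            )
        return vs


@dataclass
class VertexScalars:
    """A named per-vertex scalar array aligned to some SurfaceMesh."""

    values: np.ndarray
    name: str = "value"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("vertex scalars must be 1-D")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CohortTable:
    """Subject bookkeeping for paired and two-group designs.

    One row per (subject, condition); paired designs carry both the
    ``unaltered`` and ``deformed`` condition for every subject.
    """

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("subject_id", "condition", "group")

    def __post_init__(self) -> None:
        if len(self.rows):
            missing = [c for c in self.REQUIRED if c not in self.rows.columns]
            if missing:
                raise ValueError(f"cohort table missing columns {missing}")
            dup = self.rows.duplicated(subset=["subject_id", "condition"])
            if dup.any():
                raise ValueError("duplicate (subject_id, condition) rows")

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "CohortTable":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike) -> Volume:
    """Read a NIfTI-1 volume; 4-D images with trailing singleton axes are squeezed."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # corrupt / truncated file
        raise IOError(f"could not read NIfTI volume {path}: {exc}") from exc
    if data.ndim > 3:
        if all(n == 1 for n in data.shape[3:]):
            logger.warning("squeezing %d-D image %s to 3-D", data.ndim, path)
            data = data.reshape(data.shape[:3])
        else:
            raise ValueError(f"{path}: expected a 3-D image, got shape {data.shape}")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got shape {data.shape}")
    return Volume(data, np.asarray(img.affine))


def write_volume(volume: Volume, path: str | os.PathLike) -> None:
    """Write a Volume as NIfTI-1; the data array round-trips bit-exactly."""
    img = nib.Nifti1Image(np.asarray(volume.data), volume.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# meshes (ASCII OFF)
# ---------------------------------------------------------------------------

def write_mesh(mesh: SurfaceMesh, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {len(mesh.faces)} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_mesh(path: str | os.PathLike) -> SurfaceMesh:
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens or tokens[0] != "OFF":
        raise ValueError(f"{path}: not an ASCII OFF mesh")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4
    verts = np.array(tokens[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    faces = np.empty((nf, 3), dtype=int)
    for i in range(nf):
        cnt = int(tokens[pos])
        if cnt != 3:
            raise ValueError(f"{path}: only triangle faces supported")
        faces[i] = [int(t) for t in tokens[pos + 1 : pos + 4]]
        pos += 1 + cnt
    return SurfaceMesh(verts, faces)


# ---------------------------------------------------------------------------
# per-vertex tables
# ---------------------------------------------------------------------------

def read_vertex_table(path: str | os.PathLike, name: str = "value") -> VertexScalars:
    """Read per-vertex scalars from delimited text.

    Accepts one value per line, or two columns ``index<TAB>value`` with a
    gap-free 0-based index.  Lines starting with ``#`` and a single header
    line of non-numeric tokens are ignored.
    """
    values: list[float] = []
    indices: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            try:
                nums = [float(p) for p in parts]
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric entry {line!r}")
            if len(nums) == 1:
                values.append(nums[0])
            elif len(nums) == 2:
                indices.append(int(nums[0]))
                values.append(nums[1])
            else:
                raise ValueError(f"{path}:{lineno}: expected 1 or 2 columns")
    if not values:
        raise ValueError(f"{path}: empty vertex table")
    if indices:
        if sorted(indices) != list(range(len(indices))):
            raise ValueError(f"{path}: index column has gaps or duplicates")
        values = [v for _, v in sorted(zip(indices, values))]
    return VertexScalars(np.array(values, dtype=float), name)


def write_vertex_table(scalars: VertexScalars, path: str | os.PathLike) -> None:
    np.savetxt(path, scalars.values, fmt="%.9g")


# ---------------------------------------------------------------------------
# detection reports
# ---------------------------------------------------------------------------

def write_report(report, path: str | os.PathLike) -> None:
    """Write a DetectionReport as TSV: one summary row then scattergram rows."""
    with open(path, "w") as fh:
        fh.write("threshold\tTP\tFP\tTN\tFN\tsensitivity\tspecificity\n")
        sens = "nan" if report.sensitivity is None else f"{report.sensitivity:.9g}"
        spec = "nan" if report.specificity is None else f"{report.specificity:.9g}"
        fh.write(
            f"{report.threshold_t:.9g}\t{report.tp}\t{report.fp}\t{report.tn}\t"
            f"{report.fn}\t{sens}\t{spec}\n"
        )
        fh.write("vertex\tdistance_mm\tt\tsignificant\n")
        for row in report.scattergram.itertuples(index=False):
            fh.write(f"{row.vertex}\t{row.distance_mm:.6g}\t{row.t:.9g}\t{int(row.significant)}\n")


def read_report(path: str | os.PathLike):
    """Parse a report written by :func:`write_report` back into a DetectionReport."""
    from .surfstats import DetectionReport  # local import to avoid a cycle

    with open(path) as fh:
        lines = fh.read().splitlines()
    summary = lines[1].split("\t")
    thr, tp, fp, tn, fn = (
        float(summary[0]),
        int(summary[1]),
        int(summary[2]),
        int(summary[3]),
        int(summary[4]),
    )
    rows = []
    for line in lines[3:]:
        v, d, t, s = line.split("\t")
        rows.append((int(v), float(d), float(t), bool(int(s))))
    scat = pd.DataFrame(rows, columns=["vertex", "distance_mm", "t", "significant"])
    return DetectionReport(threshold_t=thr, tp=tp, fp=fp, tn=tn, fn=fn, scattergram=scat)
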