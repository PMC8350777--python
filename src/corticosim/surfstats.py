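"""Vertex-wise statistics on surface data: smoothing, CoV, GLMs, detection.

The battery mirrors standard surface-based morphometry practice:

* Gaussian-equivalent smoothing of per-vertex data by iterated
  nearest-neighbour diffusion on the mesh graph, parameterised by FWHM in mm;
* the coefficient of variation (test-retest reliability) across repeated
  scans;
* vertex-wise GLMs — the paired design ``1 + condition + subject`` (whose
  condition contrast is exactly the paired t-test on per-subject
  differences) and the independent two-group pooled-variance t-test;
* Bonferroni thresholding, lesion labels from an ROI, sensitivity and
  specificity of detection, distance scattergrams and ROC curves.

Models follow the estimator/results idiom: build a :class:`PairedSurfaceGLM`
or :class:`IndependentSurfaceGLM` from data matrices, call ``fit()`` and
interrogate the returned :class:`TMap` (t, p, df, ``summary()``,
``detection_report()``, ``roc()``).  Plain functions ``glm_paired`` and
``glm_independent`` wrap the same computation for one-liners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .core_io import SurfaceMesh, VertexScalars
from .lesion import ROISpec

__all__ = [
    "SmoothingParams",
    "smooth_vertex_data",
    "cov_map",
    "TMap",
    "PairedSurfaceGLM",
    "IndependentSurfaceGLM",
    "glm_paired",
    "glm_independent",
    "bonferroni_threshold",
    "vertex_labels_from_roi",
    "DetectionReport",
    "detection_report",
    "roc_curve",
]


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoothingParams:
    """Surface smoothing strength as a Gaussian-kernel FWHM in mm."""

    fwhm_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")

    @property
    def sigma_mm(self) -> float:
        return self.fwhm_mm / 2.354820045  # 2*sqrt(2*ln 2)


def _diffusion_matrix(mesh: SurfaceMesh, w: float = 0.5) -> sparse.csr_matrix:
    """One diffusion step ``I + (w/d_max)(A - D)``: symmetric, doubly stochastic.

    Symmetry makes the step mass-conserving (column sums are one) and keeps
    constants fixed; on a regular mesh it equals the familiar
    ``(1-w)*v + w*mean(neighbours)`` update.
    """
    e = mesh.edges
    n = mesh.n_vertices
    deg = np.bincount(e.ravel(), minlength=n)
    if (deg == 0).any():
        warnings.warn("mesh has isolated vertices; they are left unsmoothed", stacklevel=2)
    d_max = max(int(deg.max()), 1)
    a = w / d_max
    rows = np.concatenate([e[:, 0], e[:, 1], np.arange(n)])
    cols = np.concatenate([e[:, 1], e[:, 0], np.arange(n)])
    vals = np.concatenate([np.full(2 * len(e), a), 1.0 - a * deg])
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def smoothing_iterations(mesh: SurfaceMesh, fwhm_mm: float, w: float = 0.5) -> int:
    """Iteration count whose accumulated variance matches the requested kernel.

    ``n = round(sigma^2 / (h^2 * w * (1 - w/2)))`` with mean edge length
    ``h``; a declared convention matching the variance accumulation of
    iterated local averaging, with a floor of one iteration for any positive
    FWHM.
    """
    if fwhm_mm == 0:
        return 0
    sigma2 = SmoothingParams(fwhm_mm).sigma_mm ** 2
    h2 = mesh.mean_edge_length_mm ** 2
    return max(1, int(round(sigma2 / (h2 * w * (1.0 - w / 2.0)))))


def smooth_vertex_data(
    mesh: SurfaceMesh, values: VertexScalars | np.ndarray, fwhm_mm: float, w: float = 0.5
) -> VertexScalars:
    """Smooth per-vertex data to an approximate Gaussian FWHM on the mesh.

    ``fwhm_mm = 0`` returns the input unchanged.  The symmetric diffusion
    step conserves the vertex sum to floating-point accuracy.
    """
    name = values.name if isinstance(values, VertexScalars) else "value"
    v = np.asarray(values.values if isinstance(values, VertexScalars) else values, dtype=float)
    if len(v) != mesh.n_vertices:
        raise ValueError("values are not aligned with the mesh")
    n_iter = smoothing_iterations(mesh, fwhm_mm, w)
    if n_iter == 0:
        return mesh.attach(v.copy(), name)
    m = _diffusion_matrix(mesh, w)
    for _ in range(n_iter):
        v = m @ v
    return mesh.attach(v, name)


def smooth_matrix(mesh: SurfaceMesh, mat: np.ndarray, fwhm_mm: float, w: float = 0.5) -> np.ndarray:
    """Smooth each row of a (scans x vertices) matrix."""
    n_iter = smoothing_iterations(mesh, fwhm_mm, w)
    if n_iter == 0:
        return np.array(mat, dtype=float, copy=True)
    m = _diffusion_matrix(mesh, w)
    out = np.asarray(mat, dtype=float).T
    for _ in range(n_iter):
        out = m @ out
    return out.T


# ---------------------------------------------------------------------------
# coefficient of variation
# ---------------------------------------------------------------------------

def cov_map(thickness_matrix: np.ndarray, name: str = "cov") -> VertexScalars:
    """Per-vertex coefficient of variation across scans (rows).

    Sample SD (n-1 denominator) divided by the mean.  Vertices with zero
    mean are undefined and flagged as NaN.
    """
    x = np.asarray(thickness_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (scans x vertices) matrix with >= 2 scans")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    out = np.full(x.shape[1], np.nan)
    ok = mean != 0
    out[ok] = sd[ok] / mean[ok]
    if not ok.all():
        warnings.warn(f"CoV undefined at {int((~ok).sum())} zero-mean vertices", stacklevel=2)
    return VertexScalars(out, name)


# ---------------------------------------------------------------------------
# GLMs
# ---------------------------------------------------------------------------

@dataclass
class TMap:
    """Vertex-wise GLM results: t, two-tailed uncorrected p, and diagnostics.

    ``zero_variance`` flags vertices where the residual variance vanished;
    there t is 0 (zero effect) or signed infinity (nonzero effect) with p of
    1 or 0 respectively.
    """

    t: VertexScalars
    p: VertexScalars
    df: int
    design: str
    n_vertices: int = 0
    zero_variance: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    mean_effect: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.n_vertices = len(self.t.values)

    def bonferroni_threshold(self, alpha: float = 0.05) -> float:
        return bonferroni_threshold(alpha, self.n_vertices, self.df)

    def detection_report(
        self,
        labels: VertexScalars | np.ndarray,
        mesh: SurfaceMesh,
        center_world,
        threshold: float | None = None,
        alpha: float = 0.05,
    ) -> "DetectionReport":
        thr = self.bonferroni_threshold(alpha) if threshold is None else threshold
        return detection_report(self, thr, labels, mesh, center_world)

    def roc(self, labels: VertexScalars | np.ndarray):
        return roc_curve(self, labels)

    def summary(self) -> str:
        t = self.t.values
        lines = [
            f"Vertex-wise GLM ({self.design} design)",
            f"  vertices:            {self.n_vertices}",
            f"  degrees of freedom:  {self.df}",
            f"  max |t|:             {np.nanmax(np.abs(t)):.3f}",
            f"  min uncorrected p:   {np.nanmin(self.p.values):.3e}",
            f"  Bonferroni t (0.05): {self.bonferroni_threshold(0.05):.3f}",
            f"  zero-variance flags: {int(self.zero_variance.sum())}",
        ]
        return "\n".join(lines)


def _t_to_p(t: np.ndarray, df: int) -> np.ndarray:
    return 2.0 * stats.t.sf(np.abs(t), df)


class PairedSurfaceGLM:
    """Paired design ``1 + condition + subject`` on per-vertex data.

    With one intercept per subject the condition contrast reduces exactly to
    the paired t-test on per-subject differences: ``t = mean(d) / (sd(d)/
    sqrt(n))`` with ``df = n - 1``.
    """

    def __init__(self, deformed: np.ndarray, unaltered: np.ndarray,
                 mesh: SurfaceMesh | None = None, fwhm_mm: float = 0.0):
        deformed = np.asarray(deformed, dtype=float)
        unaltered = np.asarray(unaltered, dtype=float)
        if deformed.shape != unaltered.shape:
            raise ValueError("paired matrices must have identical shape")
        if deformed.ndim != 2 or deformed.shape[0] < 2:
            raise ValueError("need >= 2 subjects (rows)")
        if fwhm_mm > 0:
            if mesh is None:
                raise ValueError("smoothing requires the mesh")
            deformed = smooth_matrix(mesh, deformed, fwhm_mm)
            unaltered = smooth_matrix(mesh, unaltered, fwhm_mm)
        self.deformed, self.unaltered = deformed, unaltered
        self.mesh, self.fwhm_mm = mesh, fwhm_mm

    def fit(self) -> TMap:
        d = self.deformed - self.unaltered
        n = d.shape[0]
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        # relative tolerance: rounding noise on a constant offset is still
        # "zero variance" for the degenerate-case contract
        zero = (sd == 0) | (sd <= np.abs(mean) * 1e-12)
        t = np.zeros(d.shape[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            t[~zero] = mean[~zero] / (sd[~zero] / np.sqrt(n))
        t[zero] = np.where(mean[zero] == 0, 0.0, np.sign(mean[zero]) * np.inf)
        df = n - 1
        p = _t_to_p(t, df)
        p[zero] = np.where(mean[zero] == 0, 1.0, 0.0)
        if zero.any():
            warnings.warn(f"zero-variance differences at {int(zero.sum())} vertices", stacklevel=2)
        return TMap(VertexScalars(t, "t"), VertexScalars(p, "p"), df, "paired",
                    zero_variance=zero, mean_effect=mean)


class IndependentSurfaceGLM:
    """Two-group pooled-variance t-test per vertex, ``df = n1 + n2 - 2``."""

    def __init__(self, group1: np.ndarray, group2: np.ndarray,
                 mesh: SurfaceMesh | None = None, fwhm_mm: float = 0.0):
        group1 = np.asarray(group1, dtype=float)
        group2 = np.asarray(group2, dtype=float)
        if group1.ndim != 2 or group2.ndim != 2 or group1.shape[1] != group2.shape[1]:
            raise ValueError("groups must be 2-D with a common vertex count")
        if group1.shape[0] < 2 or group2.shape[0] < 2:
            raise ValueError("each group needs >= 2 subjects")
        if fwhm_mm > 0:
            if mesh is None:
                raise ValueError("smoothing requires the mesh")
            group1 = smooth_matrix(mesh, group1, fwhm_mm)
            group2 = smooth_matrix(mesh, group2, fwhm_mm)
        self.group1, self.group2 = group1, group2
        self.mesh, self.fwhm_mm = mesh, fwhm_mm

    def fit(self) -> TMap:
        x1, x2 = self.group1, self.group2
        n1, n2 = x1.shape[0], x2.shape[0]
        m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
        v1, v2 = x1.var(axis=0, ddof=1), x2.var(axis=0, ddof=1)
        df = n1 + n2 - 2
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
        diff = m1 - m2
        zero = (se == 0) | (se <= np.abs(diff) * 1e-12)
        t = np.zeros_like(diff)
        with np.errstate(divide="ignore", invalid="ignore"):
            t[~zero] = diff[~zero] / se[~zero]
        t[zero] = np.where(diff[zero] == 0, 0.0, np.sign(diff[zero]) * np.inf)
        p = _t_to_p(t, df)
        p[zero] = np.where(diff[zero] == 0, 1.0, 0.0)
        if zero.any():
            warnings.warn(f"zero pooled variance at {int(zero.sum())} vertices", stacklevel=2)
        return TMap(VertexScalars(t, "t"), VertexScalars(p, "p"), df, "independent",
                    zero_variance=zero, mean_effect=diff)


def glm_paired(deformed: np.ndarray, unaltered: np.ndarray, **kwargs) -> TMap:
    """Paired vertex-wise GLM; see :class:`PairedSurfaceGLM`."""
    return PairedSurfaceGLM(deformed, unaltered, **kwargs).fit()


def glm_independent(group1: np.ndarray, group2: np.ndarray, **kwargs) -> TMap:
    """Two-sample vertex-wise GLM; see :class:`IndependentSurfaceGLM`."""
    return IndependentSurfaceGLM(group1, group2, **kwargs).fit()


# ---------------------------------------------------------------------------
# thresholds, labels, detection
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, n_vertices: int, df: float) -> float:
    """Two-tailed t threshold at the Bonferroni-corrected level ``alpha/n``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_vertices < 1:
        raise ValueError("n_vertices must be >= 1")
    q = 1.0 - alpha / (2.0 * n_vertices)
    if np.isinf(df):
        return float(stats.norm.ppf(q))
    return float(stats.t.ppf(q, df))


def vertex_labels_from_roi(mesh: SurfaceMesh, roi_spec: ROISpec) -> VertexScalars:
    """Binary lesion labels: 1 where the vertex lies inside the ROI solid."""
    labels = roi_spec.contains(mesh.vertices).astype(float)
    if labels.sum() == 0:
        warnings.warn("ROI does not intersect the surface: zero lesion labels", stacklevel=2)
    return mesh.attach(labels, "label")


@dataclass
class DetectionReport:
    """Lesion-detection confusion counts, rates and the distance scattergram.

    ``sensitivity``/``specificity`` are ``None`` when their denominator is
    empty (no lesion vertices, or none outside the lesion).
    """

    threshold_t: float
    tp: int
    fp: int
    tn: int
    fn: int
    scattergram: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def sensitivity(self) -> float | None:
        return None if self.tp + self.fn == 0 else self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return None if self.tn + self.fp == 0 else self.tn / (self.tn + self.fp)


def detection_report(
    tmap: TMap,
    threshold: float,
    labels: VertexScalars | np.ndarray,
    mesh: SurfaceMesh | None = None,
    center_world=None,
) -> DetectionReport:
    """Score |t| >= threshold against binary lesion labels.

    The scattergram carries each vertex's Euclidean world-mm distance from
    the deformation centre, its signed t and its significance flag (empty if
    no mesh/centre is given).
    """
    lab = np.asarray(labels.values if isinstance(labels, VertexScalars) else labels)
    lab = lab.astype(bool)
    t = tmap.t.values
    if len(lab) != len(t):
        raise ValueError("labels are not aligned with the t-map")
    sig = np.abs(t) >= threshold
    tp = int(np.sum(sig & lab))
    fp = int(np.sum(sig & ~lab))
    fn = int(np.sum(~sig & lab))
    tn = int(np.sum(~sig & ~lab))
    scat = pd.DataFrame()
    if mesh is not None and center_world is not None:
        dist = np.linalg.norm(mesh.vertices - np.asarray(center_world, dtype=float), axis=1)
        scat = pd.DataFrame(
            {"vertex": np.arange(len(t)), "distance_mm": dist, "t": t, "significant": sig}
        )
    return DetectionReport(threshold_t=float(threshold), tp=tp, fp=fp, tn=tn, fn=fn,
                           scattergram=scat)


def roc_curve(tmap: TMap, labels: VertexScalars | np.ndarray):
    """ROC of |t| as a lesion score: (fpr, tpr, auc) with trapezoidal AUC."""
    from sklearn import metrics

    lab = np.asarray(labels.values if isinstance(labels, VertexScalars) else labels).astype(int)
    if len(np.unique(lab)) < 2:
        raise ValueError("ROC requires both label classes")
    score = np.abs(tmap.t.values)
    score = np.where(np.isinf(score), np.nanmax(score[np.isfinite(score)], initial=0.0) + 1.0, score)
    fpr, tpr, _ = metrics.roc_curve(lab, score)
    return fpr, tpr, float(metrics.auc(fpr, tpr))
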