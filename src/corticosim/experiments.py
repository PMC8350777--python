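"""End-to-end experiment driver for the three validation designs.

Each run sweeps a grid of (ROI x contraction x FWHM) cells on phantom data
and, per cell, produces a t-map, a detection report with scattergram, and an
ROC curve, all written as TSV next to a JSON manifest that records every
parameter, seed and solver log so the run is reproducible byte for byte.

Designs
-------
``experiment1_within``
    Repeated scans of one anatomy; CoV map of the unaltered thickness plus a
    paired test of deformed vs unaltered scans (within-subject power).
``experiment2_paired``
    A between-subject cohort, each subject measured unaltered and deformed;
    paired GLM (dependent population test).
``experiment3_independent``
    The cohort split into two seeded halves, lesions applied to one half;
    independent two-group GLM.

The deformation field depends only on the ROI and contraction — never on a
particular subject's image — so it is solved once per cell and applied to
every subject, exactly as one lesion recipe is stamped onto every scan of a
registered cohort.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import core_io, lesion, phantom, surfstats, toycortex
from .core_io import SurfaceMesh, Volume, write_report

__all__ = ["ExperimentConfig", "run_experiment", "version_compare"]

DESIGNS = ("experiment1_within", "experiment2_paired", "experiment3_independent")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    design: str = "experiment2_paired"
    out_dir: str = "experiment_out"
    seed: int = 0
    n_scans: int = 5
    n_subjects: int = 20
    thickness_sd_mm: float = 0.5
    phantom: phantom.PhantomSpec = field(default_factory=phantom.PhantomSpec)
    rois: list[lesion.ROISpec] = field(
        default_factory=lambda: [lesion.ROISpec(corner_world=(8.5, -5.0, -5.0), size_mm=10.0)]
    )
    contraction_volumes: list[float] = field(default_factory=lambda: [0.4])
    fwhm_levels: list[float] = field(default_factory=lambda: [10.0])
    alpha: float = 0.05
    threshold_t: float | None = None  # override; default derives Bonferroni per mesh
    metric: str = "tlink_ray"
    solver: dict = field(default_factory=dict)  # forwarded to solve_deformation_field

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}")
        if not self.rois or not self.contraction_volumes or not self.fwhm_levels:
            raise ValueError("rois, contraction_volumes and fwhm_levels must be non-empty")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom"] = asdict(self.phantom)
        d["rois"] = [asdict(r) for r in self.rois]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            ph = dict(d["phantom"])
            for key in ("grid_shape", "center_world", "intensity_means"):
                if key in ph and isinstance(ph[key], list):
                    ph[key] = tuple(ph[key])
            d["phantom"] = phantom.PhantomSpec(**ph)
        if "rois" in d:
            d["rois"] = [
                lesion.ROISpec(**{**r, "corner_world": tuple(r["corner_world"])})
                if isinstance(r, dict) else r
                for r in d["rois"]
            ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _measure(volume: Volume, mesh: SurfaceMesh, spec: phantom.PhantomSpec, metric: str) -> np.ndarray:
    means = dict(zip(phantom.CLASS_NAMES, spec.intensity_means))
    cls = toycortex.classify_tissues(volume, means)
    res = toycortex.estimate_thickness(cls.class_maps, mesh, metric=metric,
                                       max_search_mm=4.0 * spec.thickness_mm)
    return res.thickness.values


def _solve_cell(roi: lesion.ROISpec, contraction: float, grid: Volume, solver_kwargs: dict):
    roi_mask = lesion.make_roi_mask(roi, grid)
    ring = lesion.make_tolerance_mask(roi_mask, roi.pad_mm, grid)
    free = grid.like(np.asarray(roi_mask.data, bool) | np.asarray(ring.data, bool))
    det = lesion.make_determinant_map(roi_mask, contraction, grid)
    fld = lesion.solve_deformation_field(det, free, **solver_kwargs)
    return roi_mask, fld


def run_experiment(config: ExperimentConfig) -> dict:
    """Run every (ROI x contraction x FWHM) cell of ``config``; return the manifest.

    A failed cell is logged in the manifest with its error and the run
    continues; output TSVs land under ``config.out_dir``.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    spec = config.phantom
    ph_spec = phantom.PhantomSpec(**{**asdict(spec), "seed": config.seed})

    if config.design == "experiment1_within":
        subjects = phantom.make_repeated_scans(ph_spec, config.n_scans)
    else:
        subjects = phantom.make_cohort(ph_spec, config.n_subjects, config.thickness_sd_mm)
    mesh = subjects[0].mid_surface
    grid = subjects[0].volume

    # In the paired designs the deformed condition is measured on a fresh
    # re-scan of the same anatomy (seed offset 100000 + i): both members of a
    # pair then carry independent measurement noise, as any pair of processed
    # scans does.  Without this the toy pipeline's paired differences would be
    # exactly zero away from the lesion and the t statistic degenerate.
    if config.design in ("experiment1_within", "experiment2_paired"):
        from dataclasses import replace as _replace

        scan_sources = [
            phantom.make_phantom(_replace(s.spec, seed=100000 + s.spec.seed))
            for s in subjects
        ]
    else:
        scan_sources = subjects

    group1_idx = group2_idx = None
    if config.design == "experiment3_independent":
        group1_idx, group2_idx = phantom.split_cohort(len(subjects), config.seed)

    # unaltered thickness is per subject and shared by every cell
    unaltered = np.vstack([_measure(s.volume, mesh, s.spec, config.metric) for s in subjects])

    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "design": config.design,
        "n_vertices": mesh.n_vertices,
        "cells": [],
    }
    if group1_idx is not None:
        manifest["group1"] = group1_idx.tolist()
        manifest["group2"] = group2_idx.tolist()

    if config.design == "experiment1_within":
        cov = surfstats.cov_map(unaltered)
        cov_path = os.path.join(config.out_dir, "cov_unaltered.tsv")
        core_io.write_vertex_table(cov, cov_path)
        manifest["cov_table"] = cov_path

    for roi_i, roi in enumerate(config.rois):
        for contraction in config.contraction_volumes:
            cell_base = {
                "roi_index": roi_i,
                "roi": asdict(roi),
                "contraction_volume": contraction,
            }
            try:
                if contraction != 0.0:
                    roi_used = lesion.ROISpec(**{**asdict(roi), "contraction_volume": contraction})
                    roi_mask, fld = _solve_cell(roi_used, contraction, grid, config.solver)
                    deformed_vols = [lesion.apply_deformation(s.volume, fld) for s in scan_sources]
                    solver_info = {
                        "iterations": len(fld.solver_log) - 1,
                        "final_error": fld.solver_log[-1],
                        "converged": fld.converged,
                    }
                else:
                    roi_used = roi
                    deformed_vols = [s.volume for s in scan_sources]
                    solver_info = {"null_cell": True}
                deformed = np.vstack(
                    [_measure(v, mesh, s.spec, config.metric)
                     for v, s in zip(deformed_vols, scan_sources)]
                )
                labels = surfstats.vertex_labels_from_roi(mesh, roi_used)
                center = roi_used.center_world

                for fwhm in config.fwhm_levels:
                    cell = dict(cell_base, fwhm_mm=fwhm, solver=solver_info)
                    if config.design == "experiment3_independent":
                        tmap = surfstats.glm_independent(
                            deformed[group2_idx], unaltered[group1_idx],
                            mesh=mesh, fwhm_mm=fwhm,
                        )
                    else:
                        tmap = surfstats.glm_paired(deformed, unaltered, mesh=mesh, fwhm_mm=fwhm)
                    thr = config.threshold_t
                    if thr is None:
                        thr = tmap.bonferroni_threshold(config.alpha)
                    report = tmap.detection_report(labels, mesh, center, threshold=thr)
                    tag = f"roi{roi_i}_c{contraction:g}_fwhm{fwhm:g}"
                    tmap_path = os.path.join(config.out_dir, f"tmap_{tag}.tsv")
                    core_io.write_vertex_table(tmap.t, tmap_path)
                    report_path = os.path.join(config.out_dir, f"report_{tag}.tsv")
                    write_report(report, report_path)
                    cell["outputs"] = {"tmap": tmap_path, "report": report_path}
                    cell["threshold_t"] = thr
                    cell["df"] = tmap.df
                    cell["sensitivity"] = report.sensitivity
                    cell["specificity"] = report.specificity
                    if contraction == 0.0:
                        # no true lesion was applied: sensitivity is undefined
                        cell["null_cell"] = True
                        cell["sensitivity"] = None
                    if contraction != 0.0 and labels.values.sum() > 0:
                        try:
                            fpr, tpr, auc = tmap.roc(labels)
                            roc_path = os.path.join(config.out_dir, f"roc_{tag}.tsv")
                            pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(roc_path, sep="\t", index=False)
                            cell["outputs"]["roc"] = roc_path
                            cell["auc"] = auc
                        except ValueError:
                            pass
                    manifest["cells"].append(cell)
            except Exception as exc:  # a failed cell aborts the cell, not the run
                warnings.warn(f"cell {cell_base} failed: {exc}", stacklevel=2)
                manifest["cells"].append(dict(cell_base, error=str(exc)))

    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    manifest["manifest_path"] = manifest_path
    return manifest


def version_compare(
    deformed_a: np.ndarray,
    unaltered_a: np.ndarray,
    deformed_b: np.ndarray,
    unaltered_b: np.ndarray,
    mesh: SurfaceMesh,
    rois: list[lesion.ROISpec],
    fwhm_mm: float = 0.0,
    alpha: float = 0.05,
    threshold_t: float | None = None,
) -> pd.DataFrame:
    """Side-by-side detection performance of two thickness-table sets.

    Both sets (e.g. two versions of the same external pipeline, read via
    ``core_io.read_vertex_table``) must live on the same mesh; the identical
    paired battery is run on each and per-ROI sensitivity/specificity are
    tabulated for direct comparison.
    """
    na, nb = np.asarray(deformed_a).shape[1], np.asarray(deformed_b).shape[1]
    if na != nb:
        raise ValueError(f"vertex-count mismatch between sets: A has {na}, B has {nb}")
    if na != mesh.n_vertices:
        raise ValueError(f"tables have {na} vertices but the mesh has {mesh.n_vertices}")
    rows = []
    for label, dfm, unalt in (("A", deformed_a, unaltered_a), ("B", deformed_b, unaltered_b)):
        tmap = surfstats.glm_paired(np.asarray(dfm), np.asarray(unalt), mesh=mesh, fwhm_mm=fwhm_mm)
        thr = threshold_t if threshold_t is not None else tmap.bonferroni_threshold(alpha)
        for i, roi in enumerate(rois):
            labels = surfstats.vertex_labels_from_roi(mesh, roi)
            rep = tmap.detection_report(labels, mesh, roi.center_world, threshold=thr)
            rows.append(
                {
                    "set": label,
                    "roi_index": i,
                    "threshold_t": thr,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                    "tp": rep.tp,
                    "fp": rep.fp,
                    "tn": rep.tn,
                    "fn": rep.fn,
                }
            )
    return pd.DataFrame(rows)
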