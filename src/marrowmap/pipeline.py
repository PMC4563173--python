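"""End-to-end marrow quantification: CT+PET in, volume report out.

Stage order: bone extraction -> discriminant training and voxel
classification -> islanding -> SUV conversion -> vertebral statistics ->
red-marrow threshold -> red/yellow segmentation -> volumetry -> SUV summary.
Each stage failure is re-raised naming the stage, carrying whatever partial
results earlier stages produced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .config import PipelineConfig
from .discriminant import (
    CompartmentMasks,
    HounsfieldDiscriminant,
    PosteriorMaps,
    TrainingSet,
    classify_compartments,
    posterior_map,
    train_lda,
)
from .grids import SuvCalibration, VoxelGrid, compute_suv, resample_to_grid
from .marrow import (
    MarrowSegmentation,
    VertebralStatistics,
    VolumeReport,
    compute_volumes,
    red_threshold,
    segment_marrow,
    suv_summary,
    vertebral_statistics,
)
from .segmentation import apply_islanding, extract_bone_mask

__all__ = ["PipelineStageError", "PipelineResult", "run_pipeline", "sample_training_voxels"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; ``partial`` holds earlier stages' outputs."""

    def __init__(self, stage: str, cause: Exception, partial: "PipelineResult"):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial = partial


@dataclass
class PipelineResult:
    """All intermediate and final outputs of one pipeline run."""

    config: PipelineConfig
    suv: VoxelGrid | None = None
    bone: np.ndarray | None = None
    model: HounsfieldDiscriminant | None = None
    posteriors: PosteriorMaps | None = None
    compartments_raw: CompartmentMasks | None = None
    compartments: CompartmentMasks | None = None
    vertebral_stats: VertebralStatistics | None = None
    segmentation: MarrowSegmentation | None = None
    report: VolumeReport | None = None
    stage_log: list = field(default_factory=list)

    def report_json(self) -> str:
        """Deterministic machine-readable report (no timestamps)."""
        if self.report is None:
            raise ValueError("pipeline did not reach the reporting stage")
        payload = {
            "report": self.report.to_dict(),
            "vertebral_statistics": {
                "mean_suv": self.vertebral_stats.mean_suv,
                "sd_suv": self.vertebral_stats.sd_suv,
                "voxel_count": self.vertebral_stats.voxel_count,
                "multiplier": self.vertebral_stats.multiplier,
            },
            "model": self.model.to_dict() if self.model is not None else None,
            "config": self.config.model_dump(),
            "stage_log": self.stage_log,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def sample_training_voxels(
    ct: VoxelGrid,
    cortical_mask: np.ndarray,
    trabecular_mask: np.ndarray,
    n: int = 1000,
    seed: int | None = None,
) -> TrainingSet:
    """Draw ``n`` labelled skeleton voxels for discriminant training.

    Emulates the manual labelling step: voxels are drawn uniformly without
    replacement from the union of the two label masks, keeping each voxel's
    mask label. Redrawn (up to 20 attempts) if a draw misses a class.
    """
    cortical_mask = np.asarray(cortical_mask, dtype=bool)
    trabecular_mask = np.asarray(trabecular_mask, dtype=bool)
    if np.any(cortical_mask & trabecular_mask):
        raise ValueError("cortical and trabecular training masks overlap")
    idx_c = np.flatnonzero(cortical_mask.ravel())
    idx_t = np.flatnonzero(trabecular_mask.ravel())
    pool = np.concatenate([idx_c, idx_t])
    labels_pool = np.concatenate([np.full(idx_c.size, "C"), np.full(idx_t.size, "T")])
    if pool.size < n:
        raise ValueError(f"only {pool.size} labelled voxels available, need {n}")
    rng = np.random.default_rng(seed)
    for _ in range(20):
        take = rng.choice(pool.size, size=n, replace=False)
        labels = labels_pool[take]
        if (labels == "C").sum() >= 2 and (labels == "T").sum() >= 2:
            flat = pool[take]
            values = ct.data.ravel()[flat]
            prov = np.column_stack(np.unravel_index(flat, ct.shape))
            return TrainingSet(values=values, labels=labels, provenance=prov)
    raise ValueError("could not draw a training set containing both classes")


def run_pipeline(
    ct: VoxelGrid,
    pet: VoxelGrid,
    training: TrainingSet,
    rois: Mapping[str, np.ndarray],
    config: PipelineConfig | None = None,
    calibration: SuvCalibration | None = None,
) -> PipelineResult:
    """Run the full quantification chain on a co-registered CT/PET pair.

    Parameters
    ----------
    ct, pet : VoxelGrid
        Co-registered volumes. If the PET geometry differs it is resampled
        onto the CT grid (all masks live on the CT grid). ``pet`` may
        already be in SUV; pass ``calibration`` when it is raw Bq/ml.
    training : TrainingSet
        Labelled cortical/trabecular HU samples.
    rois : mapping
        ``"vertebrae"`` (required at the thresholding stage), optional
        ``"spine"`` (defaults to the vertebral ROI) and ``"skull"``.
    """
    config = config or PipelineConfig()
    result = PipelineResult(config=config)

    def stage(name: str, fn):
        try:
            out = fn()
        except Exception as exc:
            raise PipelineStageError(name, exc, result) from exc
        result.stage_log.append(name)
        return out

    if not pet.same_geometry(ct):
        pet = stage("resample_pet", lambda: resample_to_grid(pet, ct, "trilinear"))
    if calibration is not None:
        pet = stage("compute_suv", lambda: compute_suv(pet, calibration, config.decay_correct))
    result.suv = pet

    result.bone = stage(
        "extract_bone_mask",
        lambda: extract_bone_mask(ct, config.hu_threshold, config.closing_radius_mm),
    )
    result.model = stage("train_lda", lambda: train_lda(training, prior=config.prior))
    result.posteriors = stage(
        "posterior_map", lambda: posterior_map(result.model, ct, result.bone)
    )
    result.compartments_raw = stage(
        "classify_compartments", lambda: classify_compartments(result.posteriors, result.bone)
    )
    result.compartments = stage(
        "island_filter",
        lambda: apply_islanding(
            result.compartments_raw, config.min_island, config.connectivity
        ),
    )
    trabecular = result.compartments.trabecular

    def _vert_stats():
        if "vertebrae" not in rois:
            raise ValueError("missing vertebral ROI ('vertebrae' key)")
        return vertebral_statistics(pet, trabecular, rois["vertebrae"], multiplier=config.k)

    result.vertebral_stats = stage("vertebral_statistics", _vert_stats)
    threshold = stage("red_threshold", lambda: red_threshold(result.vertebral_stats))
    skull = rois.get("skull") if config.exclude_skull else None
    result.segmentation = stage(
        "segment_marrow", lambda: segment_marrow(pet, trabecular, threshold, exclude=skull)
    )
    result.report = stage(
        "compute_volumes", lambda: compute_volumes(result.segmentation, trabecular, ct.spacing)
    )
    result.report.skull_excluded = skull is not None

    spine = rois.get("spine", rois.get("vertebrae"))
    if spine is not None:
        spinal, rob, ratio = stage(
            "suv_summary",
            lambda: suv_summary(pet, trabecular, spine, rois.get("skull")),
        )
        result.report.spinal_mean_suv = spinal
        result.report.rob_mean_suv = rob
        result.report.spine_to_rob_ratio = ratio
    return result
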