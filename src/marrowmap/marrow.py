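"""Red/yellow bone-marrow quantification from trabecular PET activity.

Bone marrow resides in the trabecular compartment. Rather than a fixed SUV
cut-off, the red (hematopoietically active) marrow is segmented with a
patient-specific statistical threshold derived from the trabecular activity
of the thoracic and lumbar vertebrae:

    threshold = SUV_vert - k * SD_vert,        k = 2.5 by default,

where SUV_vert and SD_vert are the mean and sample standard deviation of
the SUV over trabecular vertebral voxels. Trabecular voxels strictly above
the threshold are red marrow; the remainder is yellow (fatty, inactive)
marrow. Volumes are reported in millilitres.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import VoxelGrid

__all__ = [
    "VertebralStatistics",
    "MarrowSegmentation",
    "VolumeReport",
    "vertebral_statistics",
    "red_threshold",
    "segment_marrow",
    "compute_volumes",
    "suv_summary",
]


@dataclass(frozen=True)
class VertebralStatistics:
    """Mean/SD of SUV over trabecular vertebral voxels.

    ``multiplier`` is the k of the threshold formula mean - k*SD.
    """

    mean_suv: float
    sd_suv: float
    voxel_count: int
    multiplier: float = 2.5

    def __post_init__(self) -> None:
        if self.sd_suv < 0:
            raise ValueError("sd_suv must be non-negative")
        if self.voxel_count < 2:
            raise ValueError("need at least 2 vertebral trabecular voxels")
        if self.multiplier <= 0:
            raise ValueError("multiplier k must be positive")


@dataclass
class MarrowSegmentation:
    """Disjoint red/yellow partition of the analyzed trabecular region."""

    red: np.ndarray
    yellow: np.ndarray
    analyzed: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        if np.any(self.red & self.yellow):
            raise ValueError("red and yellow masks overlap")
        if np.any((self.red | self.yellow) != self.analyzed):
            raise ValueError("red and yellow masks do not partition the analyzed region")


@dataclass
class VolumeReport:
    """Marrow volumetry and SUV summary for one scan.

    ``ibv_ml`` is the full trabecular (intraosseous) bone volume; ``rbv_ml``
    and ``ybv_ml`` partition the analyzed region (trabecular minus any
    exclusions, e.g. the skull).
    """

    ibv_ml: float
    rbv_ml: float
    ybv_ml: float
    red_fraction: float
    threshold_suv: float
    spinal_mean_suv: float = math.nan
    rob_mean_suv: float = math.nan
    spine_to_rob_ratio: float = math.nan
    skull_excluded: bool = False

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.red_fraction <= 1 + 1e-9):
            raise ValueError(f"red_fraction out of [0, 1]: {self.red_fraction}")
        if self.ibv_ml + 1e-9 < max(self.rbv_ml, self.ybv_ml):
            raise ValueError("trabecular volume cannot be smaller than its parts")

    def to_dict(self) -> dict:
        return {
            "ibv_ml": self.ibv_ml,
            "rbv_ml": self.rbv_ml,
            "ybv_ml": self.ybv_ml,
            "red_fraction": self.red_fraction,
            "threshold_suv": self.threshold_suv,
            "spinal_mean_suv": self.spinal_mean_suv,
            "rob_mean_suv": self.rob_mean_suv,
            "spine_to_rob_ratio": self.spine_to_rob_ratio,
            "skull_excluded": self.skull_excluded,
        }


def vertebral_statistics(
    suv: VoxelGrid,
    trabecular: np.ndarray,
    vertebral_roi: np.ndarray,
    multiplier: float = 2.5,
) -> VertebralStatistics:
    """Mean and sample SD of SUV over trabecular voxels inside the vertebral ROI.

    The sample standard deviation uses the n-1 denominator.
    """
    region = np.asarray(trabecular, dtype=bool) & np.asarray(vertebral_roi, dtype=bool)
    n = int(region.sum())
    if n < 2:
        raise ValueError(
            "vertebral ROI intersects fewer than 2 trabecular voxels; "
            "check that the ROI covers trabecular bone"
        )
    values = suv.data[region]
    return VertebralStatistics(
        mean_suv=float(values.mean()),
        sd_suv=float(values.std(ddof=1)),
        voxel_count=n,
        multiplier=multiplier,
    )


def red_threshold(stats: VertebralStatistics) -> float:
    """Red-marrow SUV threshold, mean - k*SD of the vertebral activity.

    May be negative for dispersed vertebral activity; since SUV is
    non-negative, a negative threshold classifies every analyzed voxel as
    red. That is legal, documented behaviour and triggers a warning.
    """
    threshold = stats.mean_suv - stats.multiplier * stats.sd_suv
    if threshold < 0:
        warnings.warn(
            f"red-marrow threshold {threshold:.4g} is negative "
            f"(mean {stats.mean_suv:.4g}, k={stats.multiplier:g}, SD {stats.sd_suv:.4g}); "
            "every analyzed voxel will be classified red",
            stacklevel=2,
        )
    return float(threshold)


def segment_marrow(
    suv: VoxelGrid,
    trabecular: np.ndarray,
    threshold: float,
    exclude: np.ndarray | None = None,
) -> MarrowSegmentation:
    """Partition trabecular voxels into red (SUV > threshold) and yellow.

    ``exclude`` removes a region (typically the skull, whose trabecular
    content is mostly brain misclassified as bone) from the analysis. Voxels
    exactly at the threshold count as yellow: red marrow is strictly *above*
    the threshold.
    """
    trabecular = np.asarray(trabecular, dtype=bool)
    if trabecular.shape != suv.shape:
        raise ValueError("trabecular mask geometry does not match the SUV grid")
    analyzed = trabecular.copy()
    if exclude is not None:
        exclude = np.asarray(exclude, dtype=bool)
        if exclude.shape != suv.shape:
            raise ValueError("exclusion mask geometry does not match the SUV grid")
        analyzed &= ~exclude
    red = analyzed & (suv.data > threshold)
    yellow = analyzed & ~red
    return MarrowSegmentation(red=red, yellow=yellow, analyzed=analyzed, threshold=float(threshold))


def compute_volumes(
    seg: MarrowSegmentation,
    trabecular: np.ndarray,
    spacing: tuple[float, float, float],
) -> VolumeReport:
    """Volumes in ml (voxel count x voxel volume) and the red fraction.

    The red fraction is RBV over the analyzed-region volume, so
    RBV + YBV = analyzed volume holds exactly by construction.
    """
    vox_ml = float(np.prod(spacing)) / 1000.0
    n_red = int(seg.red.sum())
    n_yellow = int(seg.yellow.sum())
    n_analyzed = int(seg.analyzed.sum())
    n_trab = int(np.asarray(trabecular, dtype=bool).sum())
    return VolumeReport(
        ibv_ml=n_trab * vox_ml,
        rbv_ml=n_red * vox_ml,
        ybv_ml=n_yellow * vox_ml,
        red_fraction=n_red / n_analyzed if n_analyzed else math.nan,
        threshold_suv=seg.threshold,
    )


def suv_summary(
    suv: VoxelGrid,
    trabecular: np.ndarray,
    spine_roi: np.ndarray,
    skull_roi: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Mean trabecular SUV in the spinal column vs the rest of the body.

    Returns ``(spinal_mean, rob_mean, ratio)`` where ROB (rest of body) is
    trabecular bone outside the spine, optionally also excluding the skull.
    """
    trabecular = np.asarray(trabecular, dtype=bool)
    spine = trabecular & np.asarray(spine_roi, dtype=bool)
    rob = trabecular & ~np.asarray(spine_roi, dtype=bool)
    if skull_roi is not None:
        rob &= ~np.asarray(skull_roi, dtype=bool)
    if not spine.any():
        raise ValueError("spine ROI contains no trabecular voxels")
    if not rob.any():
        raise ValueError("rest-of-body region is empty")
    spinal_mean = float(suv.data[spine].mean())
    rob_mean = float(suv.data[rob].mean())
    return spinal_mean, rob_mean, spinal_mean / rob_mean
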