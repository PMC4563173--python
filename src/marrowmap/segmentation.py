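"""Skeleton extraction, islanding, and classifier evaluation.

The bone compartment is extracted from CT by Hounsfield thresholding plus a
morphological closing that recaptures trabecular interiors dipping below the
threshold. After probabilistic classification (see :mod:`.discriminant`) the
trabecular mask is cleaned by *islanding*: every 3-D connected component
smaller than ``min_size`` voxels is treated as spurious and re-assigned to
the cortical compartment, using 26-neighbourhood connectivity (voxels
touching by face, edge, or corner) by default.

Classifier performance is assessed with repeated leave-one-out
cross-validation: each repetition draws a fresh random training set, every
sample in it is classified by a model refit on the remaining samples, and
accuracy, sensitivity, specificity and precision are averaged over the
repetitions (cortical is the positive class).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .discriminant import CORTICAL, TRABECULAR, CompartmentMasks, TrainingSet
from .grids import VoxelGrid

__all__ = [
    "ClassifierMetrics",
    "extract_bone_mask",
    "island_filter",
    "apply_islanding",
    "loocv_evaluate",
]

HU_MIN, HU_MAX = -1024.0, 3071.0

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class ClassifierMetrics:
    """Mean LOOCV metrics across repetitions; cortical is the positive class."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    repetitions: int
    samples_per_repetition: int
    skipped_folds: int = 0

    def __post_init__(self) -> None:
        for name in ("accuracy", "sensitivity", "specificity", "precision"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0 or math.isnan(v)):
                raise ValueError(f"{name} out of [0, 1]: {v}")
        if self.repetitions <= 0 or self.samples_per_repetition <= 0:
            raise ValueError("counts must be positive")


def extract_bone_mask(
    ct: VoxelGrid,
    hu_threshold: float = 100.0,
    closing_radius_mm: float = 3.0,
) -> np.ndarray:
    """Extract the bone compartment from a CT volume.

    Voxels at or above ``hu_threshold`` are kept, then a morphological
    closing with an ellipsoidal structuring element of the given physical
    radius fills trabecular interiors whose noisy HU dips below the
    threshold. ``closing_radius_mm=0`` is pure thresholding.
    """
    if not (HU_MIN <= hu_threshold <= HU_MAX):
        raise ValueError(
            f"hu_threshold {hu_threshold} outside the plausible HU range "
            f"[{HU_MIN:g}, {HU_MAX:g}]"
        )
    if closing_radius_mm < 0:
        raise ValueError("closing_radius_mm must be non-negative")
    mask = ct.data >= hu_threshold
    if closing_radius_mm == 0 or not mask.any():
        return mask
    structure = _ellipsoid_structure(closing_radius_mm, ct.spacing)
    # pad so the border behaves like open background: keeps closing extensive
    pad = [(s // 2, s // 2) for s in structure.shape]
    padded = np.pad(mask, pad, mode="constant", constant_values=False)
    closed = ndimage.binary_closing(padded, structure=structure)
    sl = tuple(slice(p, d + p) for (p, _), d in zip(pad, mask.shape))
    return closed[sl] | mask


def _ellipsoid_structure(radius_mm: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """Ellipsoidal structuring element with a physical radius per axis."""
    radii_vox = np.maximum(np.asarray(radius_mm) / np.asarray(spacing), 0.0)
    half = np.ceil(radii_vox).astype(int)
    grids = np.indices(2 * half + 1).astype(float) - half[:, None, None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = sum(
            np.where(radii_vox[a] > 0, (grids[a] / max(radii_vox[a], 1e-12)) ** 2,
                     np.where(grids[a] == 0, 0.0, np.inf))
            for a in range(3)
        )
    return r2 <= 1.0 + 1e-9


def island_filter(mask: np.ndarray, min_size: int = 10, connectivity: int = 26) -> np.ndarray:
    """Remove connected components with fewer than ``min_size`` voxels.

    ``connectivity`` is the 3-D neighbourhood definition: 6 (faces), 18
    (faces+edges) or 26 (faces+edges+corners). The output is a subset of the
    input; ``min_size=1`` is the identity.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    mask = np.asarray(mask, dtype=bool)
    if min_size == 1 or not mask.any():
        return mask.copy()
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel())
    keep = counts >= min_size
    keep[0] = False
    return keep[labels]


def apply_islanding(
    masks: CompartmentMasks, min_size: int = 10, connectivity: int = 26
) -> CompartmentMasks:
    """Clean the trabecular mask; removed islands become cortical.

    Small trabecular components are spurious points marked erroneously as
    trabecular; re-assigning them to cortical preserves the partition of the
    bone mask.
    """
    kept = island_filter(masks.trabecular, min_size=min_size, connectivity=connectivity)
    removed = masks.trabecular & ~kept
    return CompartmentMasks(
        bone=masks.bone,
        cortical=masks.cortical | removed,
        trabecular=kept,
    )


def loocv_evaluate(
    pool: TrainingSet,
    repetitions: int = 50,
    samples_per_rep: int = 1000,
    seed: int | None = None,
    prior: float = 0.5,
) -> ClassifierMetrics:
    """Repeated leave-one-out cross-validation of the HU discriminant.

    Each repetition draws ``samples_per_rep`` labelled voxels from the pool
    without replacement, then leaves out each sample in turn, refits the
    pooled-variance discriminant on the remainder and classifies the
    held-out sample. Metrics are averaged over repetitions, with cortical as
    the positive class. Folds whose training remainder lacks a class or has
    zero pooled variance are skipped and counted.

    The refits use exact mean/variance downdates, so each repetition costs
    O(n) rather than O(n^2).
    """
    if samples_per_rep > len(pool):
        raise ValueError(
            f"samples_per_rep={samples_per_rep} exceeds pool size {len(pool)}"
        )
    if samples_per_rep < 4:
        raise ValueError("samples_per_rep must be at least 4 for leave-one-out refits")
    rng = np.random.default_rng(seed)
    log_odds = math.log(prior / (1.0 - prior))

    acc, sen, spe, pre = [], [], [], []
    skipped_total = 0
    for _ in range(repetitions):
        idx = rng.choice(len(pool), size=samples_per_rep, replace=False)
        x = pool.values[idx]
        is_c = pool.labels[idx] == CORTICAL
        pred_c, valid = _loo_predict(x, is_c, log_odds)
        skipped_total += int((~valid).sum())
        x_eval, truth, pred = x[valid], is_c[valid], pred_c[valid]
        tp = int(np.sum(pred & truth))
        tn = int(np.sum(~pred & ~truth))
        fp = int(np.sum(pred & ~truth))
        fn = int(np.sum(~pred & truth))
        n_eval = tp + tn + fp + fn
        acc.append((tp + tn) / n_eval if n_eval else np.nan)
        sen.append(tp / (tp + fn) if tp + fn else np.nan)
        spe.append(tn / (tn + fp) if tn + fp else np.nan)
        pre.append(tp / (tp + fp) if tp + fp else np.nan)
    if skipped_total:
        warnings.warn(f"skipped {skipped_total} degenerate leave-one-out folds", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns stay nan
        return ClassifierMetrics(
            accuracy=float(np.nanmean(acc)),
            sensitivity=float(np.nanmean(sen)),
            specificity=float(np.nanmean(spe)),
            precision=float(np.nanmean(pre)),
            repetitions=repetitions,
            samples_per_repetition=samples_per_rep,
            skipped_folds=skipped_total,
        )


def _loo_predict(x: np.ndarray, is_c: np.ndarray, log_odds: float):
    """Vectorised leave-one-out predictions for the 1-D pooled LDA.

    Removing sample i from its class updates that class's mean and sum of
    squared deviations in closed form:

        mu' = (n*mu - x_i) / (n - 1)
        SS' = SS - (x_i - mu)^2 * n / (n - 1)

    Returns (predicted_cortical, valid) boolean arrays; a fold is invalid
    when the remainder loses a class or its pooled variance vanishes.
    """
    n = x.size
    n_c = int(is_c.sum())
    n_t = n - n_c
    xc, xt = x[is_c], x[~is_c]
    sum_c, sum_t = xc.sum(), xt.sum()
    mu_c = sum_c / n_c if n_c else np.nan
    mu_t = sum_t / n_t if n_t else np.nan
    ss_c = float(((xc - mu_c) ** 2).sum()) if n_c else 0.0
    ss_t = float(((xt - mu_t) ** 2).sum()) if n_t else 0.0

    # per-sample class statistics after removing that sample
    mu_c_i = np.full(n, mu_c)
    mu_t_i = np.full(n, mu_t)
    ss_c_i = np.full(n, ss_c)
    ss_t_i = np.full(n, ss_t)
    valid = np.ones(n, dtype=bool)

    if n_c >= 2:
        mu_c_i[is_c] = (sum_c - x[is_c]) / (n_c - 1)
        ss_c_i[is_c] = ss_c - (x[is_c] - mu_c) ** 2 * n_c / (n_c - 1)
    else:
        valid[is_c] = False
    if n_t >= 2:
        mu_t_i[~is_c] = (sum_t - x[~is_c]) / (n_t - 1)
        ss_t_i[~is_c] = ss_t - (x[~is_c] - mu_t) ** 2 * n_t / (n_t - 1)
    else:
        valid[~is_c] = False
    if n_c == 0:
        valid[:] = False  # no cortical samples at all
    if n_t == 0:
        valid[:] = False

    sigma2 = (ss_c_i + ss_t_i) / (n - 3)
    degenerate = ~(sigma2 > 0)
    valid &= ~degenerate
    sigma2 = np.where(degenerate, 1.0, sigma2)

    # score difference L_C - L_T at the held-out value
    diff = (mu_c_i - mu_t_i) / sigma2 * x - (mu_c_i**2 - mu_t_i**2) / (2.0 * sigma2) + log_odds
    return diff >= 0, valid
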