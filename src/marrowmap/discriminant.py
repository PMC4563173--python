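"""Probabilistic linear discriminant on CT Hounsfield values.

Cortical (compact) bone shows the highest Hounsfield values on CT while the
trabecular compartment in its cavity is markedly lower.  A one-dimensional
two-class Gaussian linear discriminant with pooled within-class variance
exploits this: for class k with mean mu_k and pooled variance sigma^2 the
discriminant function is

    d_k(h) = alpha_k + beta_k * h,   beta_k = mu_k / sigma^2,
                                     alpha_k = -mu_k^2 / (2 sigma^2),

and the linear score adds the log class prior,

    L_k(h) = d_k(h) + log(p_prior).

Softmax over the two scores gives per-voxel posterior probabilities for the
cortical and trabecular classes; the larger posterior decides the voxel.
With equal priors the decision boundary sits at the midpoint of the two
class means.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .grids import VoxelGrid

__all__ = [
    "TrainingSet",
    "HounsfieldDiscriminant",
    "LdaModel",
    "PosteriorMaps",
    "CompartmentMasks",
    "train_lda",
    "linear_scores",
    "posterior_map",
    "classify_compartments",
]

CORTICAL = "C"
TRABECULAR = "T"


@dataclass(frozen=True)
class TrainingSet:
    """Labelled Hounsfield samples for training the discriminant.

    ``values`` are HU, ``labels`` are "C" (cortical) / "T" (trabecular).
    ``provenance`` optionally records the (i, j, k) voxel index each sample
    was drawn from.
    """

    values: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        labels = np.asarray(self.labels).ravel()
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        if values.shape != labels.shape:
            raise ValueError("values and labels must have equal length")
        unique = set(np.unique(labels).tolist())
        if unique != {CORTICAL, TRABECULAR}:
            raise ValueError(
                f"training set must contain both labels {{'C','T'}}, got {sorted(unique)}"
            )
        for lab in (CORTICAL, TRABECULAR):
            if int(np.sum(labels == lab)) < 2:
                raise ValueError(
                    f"need at least 2 samples of class {lab!r} to estimate pooled variance"
                )

    def __len__(self) -> int:
        return self.values.size


class HounsfieldDiscriminant(ClassifierMixin, BaseEstimator):
    """Two-class 1-D Gaussian LDA with pooled within-class variance.

    scikit-learn compatible classifier over a single Hounsfield-value
    feature. The pooled variance uses the unbiased N-2 denominator.

    Parameters
    ----------
    prior : float, default 0.5
        Prior probability of the cortical class, in the open interval (0, 1).
        The trabecular prior is its complement.
    cortical_label, trabecular_label : str
        The two class labels expected in ``y``.

    Attributes
    ----------
    mean_cortical_, mean_trabecular_ : float
        Class means in HU.
    pooled_variance_ : float
        Pooled within-class variance, HU^2.
    alpha_cortical_, beta_cortical_, alpha_trabecular_, beta_trabecular_ : float
        Discriminant coefficients.
    decision_boundary_ : float
        HU value where the two linear scores are equal.
    classes_ : ndarray
        The two class labels, sklearn-style.
    """

    def __init__(
        self,
        prior: float = 0.5,
        cortical_label: str = CORTICAL,
        trabecular_label: str = TRABECULAR,
    ) -> None:
        self.prior = prior
        self.cortical_label = cortical_label
        self.trabecular_label = trabecular_label

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y) -> "HounsfieldDiscriminant":
        if not (0.0 < self.prior < 1.0):
            raise ValueError(f"prior must lie in (0, 1), got {self.prior}")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError(f"expected a single HU feature, got {X.shape[1]} columns")
            X = X[:, 0]
        elif X.ndim != 1:
            raise ValueError(f"X must be 1-D or a single-column 2-D array, got ndim={X.ndim}")
        y = np.asarray(y).ravel()
        if X.shape != y.shape:
            raise ValueError("X and y length mismatch")

        mask_c = y == self.cortical_label
        mask_t = y == self.trabecular_label
        n_c, n_t = int(mask_c.sum()), int(mask_t.sum())
        if n_c + n_t != y.size:
            extra = sorted(set(np.unique(y)) - {self.cortical_label, self.trabecular_label})
            raise ValueError(f"unexpected labels in y: {extra}")
        if n_c < 2 or n_t < 2:
            raise ValueError("each class needs at least 2 samples")

        xc, xt = X[mask_c], X[mask_t]
        mu_c, mu_t = float(xc.mean()), float(xt.mean())
        ss = float(((xc - mu_c) ** 2).sum() + ((xt - mu_t) ** 2).sum())
        sigma2 = ss / (n_c + n_t - 2)
        if sigma2 <= 0 or not math.isfinite(sigma2):
            raise ValueError(
                "degenerate training set: pooled within-class variance is zero, "
                "the decision boundary is undefined"
            )

        self.classes_ = np.array([self.cortical_label, self.trabecular_label])
        self.n_features_in_ = 1
        self.mean_cortical_ = mu_c
        self.mean_trabecular_ = mu_t
        self.pooled_variance_ = sigma2
        self.beta_cortical_ = mu_c / sigma2
        self.alpha_cortical_ = -(mu_c**2) / (2.0 * sigma2)
        self.beta_trabecular_ = mu_t / sigma2
        self.alpha_trabecular_ = -(mu_t**2) / (2.0 * sigma2)
        return self

    @property
    def decision_boundary_(self) -> float:
        """HU value at which L_C = L_T (class priors included)."""
        check_is_fitted(self, "pooled_variance_")
        dbeta = self.beta_cortical_ - self.beta_trabecular_
        if dbeta == 0:
            raise ValueError("class means coincide; boundary undefined")
        log_odds = math.log((1.0 - self.prior) / self.prior)
        return (self.alpha_trabecular_ - self.alpha_cortical_ + log_odds) / dbeta

    def decision_function(self, X) -> np.ndarray:
        """Score difference L_C - L_T; positive means cortical."""
        hv = self._as_hu(X)
        l_c, l_t = self.scores(hv)
        return l_c - l_t

    def scores(self, hv) -> tuple[np.ndarray, np.ndarray]:
        """Linear scores (L_C, L_T) for Hounsfield values ``hv``."""
        check_is_fitted(self, "pooled_variance_")
        hv = np.asarray(hv, dtype=float)
        l_c = self.alpha_cortical_ + self.beta_cortical_ * hv + math.log(self.prior)
        l_t = self.alpha_trabecular_ + self.beta_trabecular_ * hv + math.log(1.0 - self.prior)
        return l_c, l_t

    def predict_proba(self, X) -> np.ndarray:
        """Posterior probabilities, columns ordered as ``classes_``.

        Computed through the logistic of the score difference, which is the
        overflow-safe form of softmax over two scores; the two columns sum
        to 1 exactly in floating point.
        """
        diff = self.decision_function(X)
        p_c = expit(diff)
        return np.column_stack([p_c, 1.0 - p_c])

    def predict(self, X) -> np.ndarray:
        """Class of the larger posterior; exact ties go to cortical."""
        diff = self.decision_function(X)
        out = np.where(diff >= 0, self.classes_[0], self.classes_[1])
        return np.asarray(out)

    @staticmethod
    def _as_hu(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            return X[:, 0]
        return X

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "pooled_variance_")
        return {
            "alpha_cortical": self.alpha_cortical_,
            "beta_cortical": self.beta_cortical_,
            "alpha_trabecular": self.alpha_trabecular_,
            "beta_trabecular": self.beta_trabecular_,
            "prior": self.prior,
            "mean_cortical": self.mean_cortical_,
            "mean_trabecular": self.mean_trabecular_,
            "pooled_variance": self.pooled_variance_,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "HounsfieldDiscriminant":
        model = cls(prior=d.get("prior", 0.5))
        model.classes_ = np.array([CORTICAL, TRABECULAR])
        model.n_features_in_ = 1
        model.alpha_cortical_ = float(d["alpha_cortical"])
        model.beta_cortical_ = float(d["beta_cortical"])
        model.alpha_trabecular_ = float(d["alpha_trabecular"])
        model.beta_trabecular_ = float(d["beta_trabecular"])
        model.mean_cortical_ = float(d.get("mean_cortical", np.nan))
        model.mean_trabecular_ = float(d.get("mean_trabecular", np.nan))
        model.pooled_variance_ = float(d.get("pooled_variance", np.nan))
        return model

    @classmethod
    def load(cls, path: str | Path) -> "HounsfieldDiscriminant":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: Alias used in pipeline signatures; a fitted discriminant *is* the model.
LdaModel = HounsfieldDiscriminant


@dataclass
class PosteriorMaps:
    """Per-voxel posterior probability volumes on the bone mask.

    Probabilities are zero outside the bone mask; on the mask the cortical
    and trabecular posteriors sum to one.
    """

    p_cortical: np.ndarray
    p_trabecular: np.ndarray
    bone: np.ndarray

    def __post_init__(self) -> None:
        if not (self.p_cortical.shape == self.p_trabecular.shape == self.bone.shape):
            raise ValueError("posterior maps and bone mask must share one shape")


@dataclass
class CompartmentMasks:
    """Disjoint cortical/trabecular partition of the bone mask."""

    bone: np.ndarray
    cortical: np.ndarray
    trabecular: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.cortical & self.trabecular):
            raise ValueError("cortical and trabecular masks overlap")
        if np.any((self.cortical | self.trabecular) != self.bone):
            raise ValueError("cortical and trabecular masks do not partition the bone mask")


# -- module-level operations (thin wrappers over the estimator) ------------


def train_lda(training: TrainingSet, prior: float = 0.5) -> HounsfieldDiscriminant:
    """Fit the pooled-variance discriminant on a labelled training set."""
    return HounsfieldDiscriminant(prior=prior).fit(training.values, training.labels)


def linear_scores(model: HounsfieldDiscriminant, hv) -> tuple[np.ndarray, np.ndarray]:
    """Linear scores (L_C, L_T) = discriminant value + log prior."""
    return model.scores(hv)


def posterior_map(
    model: HounsfieldDiscriminant, ct: VoxelGrid, bone: np.ndarray
) -> PosteriorMaps:
    """Posterior probability maps for every voxel of the bone compartment."""
    bone = np.asarray(bone, dtype=bool)
    if bone.shape != ct.shape:
        raise ValueError("bone mask geometry does not match the CT grid")
    hv = ct.data[bone].astype(float)
    l_c, l_t = model.scores(hv)
    p_c_vals = expit(l_c - l_t)
    p_c = np.zeros(ct.shape, dtype=float)
    p_t = np.zeros(ct.shape, dtype=float)
    p_c[bone] = p_c_vals
    p_t[bone] = 1.0 - p_c_vals
    return PosteriorMaps(p_cortical=p_c, p_trabecular=p_t, bone=bone)


def classify_compartments(posteriors: PosteriorMaps, bone: np.ndarray) -> CompartmentMasks:
    """Assign each bone voxel to the class with the higher posterior.

    Exact ties go to cortical, which never inflates the marrow-bearing
    trabecular compartment.
    """
    bone = np.asarray(bone, dtype=bool)
    cortical = bone & (posteriors.p_cortical >= posteriors.p_trabecular)
    trabecular = bone & ~cortical
    return CompartmentMasks(bone=bone, cortical=cortical, trabecular=trabecular)
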