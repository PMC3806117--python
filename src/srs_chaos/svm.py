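"""One-against-all Gaussian-kernel SVM over the (LLE, entropy) features.

One binary soft-margin machine is trained per class (that class +1, the
rest -1) in the feature space induced by a Gaussian kernel; prediction is
the argmax of the per-class decision values.  Features are standardized by
the training mean and standard deviation — at the very large default
penalty (C = 1e7) the raw feature scales (LLE ~ 0.1, entropy ~ 0-5) would
otherwise make the kernel width meaningless.  A small ridge (``lam``) is
added to the training kernel diagonal for numerical conditioning.

The binary sub-problems are solved by scikit-learn's SVC on a precomputed
kernel matrix, which lets the diagonal regularization be applied explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import SVC

from .core import CLASSES, FeatureVector, features_to_arrays

__all__ = ["SvmConfig", "OvaSvmModel", "train_ova_svm", "svm_predict"]

DEFAULT_C = 1e7
DEFAULT_LAMBDA = 1e-7
DEFAULT_KERNEL_WIDTH = 1.0


@dataclass(frozen=True)
class SvmConfig:
    C: float = DEFAULT_C
    lam: float = DEFAULT_LAMBDA
    kernel_width: float = DEFAULT_KERNEL_WIDTH  # Gaussian sigma on standardized features
    #: solver stopping tolerance (libsvm's KKT-violation epsilon).  The
    #: default is looser than libsvm's 1e-3 because at C = 1e7 the dual
    #: gradient scale makes an absolute 1e-3 needlessly strict: reaching it
    #: costs minutes on overlapping data for no measurable accuracy change.
    tol: float = 0.1

    def __post_init__(self) -> None:
        if self.C <= 0 or self.kernel_width <= 0:
            raise ValueError("C and kernel_width must be positive")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class OvaSvmModel:
    """Trained one-against-all model: one binary machine per class."""

    config: SvmConfig
    classes: tuple[str, ...]
    feature_mean: np.ndarray
    feature_std: np.ndarray
    X_train: np.ndarray  # standardized training features (kernel expansion points)
    machines: dict[str, SVC] = field(default_factory=dict)

    @property
    def gamma(self) -> float:
        return 1.0 / (2.0 * self.config.kernel_width**2)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_mean) / self.feature_std

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Per-class decision values, shape (n, k); column order = self.classes."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        K = rbf_kernel(self._standardize(X), self.X_train, gamma=self.gamma)
        return np.column_stack([self.machines[c].decision_function(K) for c in self.classes])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax over decision values; ties break toward the lower class index."""
        dv = self.decision_values(X)
        return np.asarray(self.classes)[np.argmax(dv, axis=1)]


def train_ova_svm(
    features: list[FeatureVector] | tuple[np.ndarray, np.ndarray],
    config: SvmConfig | None = None,
) -> OvaSvmModel:
    """Fit the three one-against-all machines.

    Accepts either a list of FeatureVector or an (X, y) pair.  Every class
    in ``CLASSES`` must be present in the training labels.
    """
    cfg = config or SvmConfig()
    if isinstance(features, tuple):
        X, y = features
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
    else:
        X, y = features_to_arrays(features)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite training features")
    present = set(np.unique(y))
    for c in CLASSES:
        if c not in present:
            raise ValueError(f"class {c!r} absent from the training data")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Xs = (X - mean) / std
    model = OvaSvmModel(
        config=cfg,
        classes=CLASSES,
        feature_mean=mean,
        feature_std=std,
        X_train=Xs,
    )
    K = rbf_kernel(Xs, Xs, gamma=model.gamma)
    K[np.diag_indices_from(K)] += cfg.lam
    for c in CLASSES:
        y_bin = np.where(y == c, 1.0, -1.0)
        svc = SVC(C=cfg.C, kernel="precomputed", tol=cfg.tol)
        svc.fit(K, y_bin)
        model.machines[c] = svc
    return model


def svm_predict(model: OvaSvmModel, feature: FeatureVector | np.ndarray) -> dict:
    """Classify a single feature vector.

    Returns {"label": predicted class, "decision_values": per-class scores}.
    """
    x = feature.xy if isinstance(feature, FeatureVector) else np.asarray(feature, dtype=float)
    dv = model.decision_values(x)[0]
    return {"label": model.classes[int(np.argmax(dv))], "decision_values": dict(zip(model.classes, dv))}
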