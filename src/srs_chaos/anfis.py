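"""First-order Sugeno ANFIS with generalized-bell memberships and hybrid learning.

Network structure (two inputs x = LLE, y = entropy; g membership functions
per input; g*g rules, one per premise combination):

1. membership layer  mu_A(x), mu_B(y) with generalized bells
   mu(v) = 1 / (1 + ((v - c)/a)^(2b))
2. rule layer        w_r = mu_Ai(x) * mu_Bj(y)          (product t-norm)
3. normalization     wbar_r = w_r / sum_r w_r
4. consequent layer  f_r = p_r x + q_r y + r_r          (first order)
5. output            yhat = sum_r wbar_r f_r

Hybrid learning alternates an exact linear least-squares solve of the
consequent parameters (premises frozen) with a gradient-descent step on the
premise parameters (a, b, c); the gradient step is backtracked so the
recorded training error never increases.  Classification uses a single
crisp output regressed on class codes 1/2/3 and decoded to the nearest
code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import CLASS_TO_CODE, CODE_TO_CLASS, FeatureVector, features_to_arrays

logger = logging.getLogger(__name__)

__all__ = [
    "AnfisConfig",
    "AnfisModel",
    "train_anfis",
    "anfis_predict",
    "labels_to_codes",
    "decode_codes",
]

DEFAULT_EPOCHS = 10
DEFAULT_MFS_PER_INPUT = 3
DEFAULT_LEARNING_RATE = 0.01


def labels_to_codes(y: np.ndarray) -> np.ndarray:
    return np.array([CLASS_TO_CODE[label] for label in y], dtype=float)


def decode_codes(crisp: np.ndarray) -> np.ndarray:
    """Nearest class code in {1,2,3}, clamped; half-way points round down."""
    out = np.asarray(crisp, dtype=float)
    return (1 + (out > 1.5).astype(int) + (out > 2.5).astype(int)).astype(int)


@dataclass(frozen=True)
class AnfisConfig:
    epochs: int = DEFAULT_EPOCHS
    mfs_per_input: int = DEFAULT_MFS_PER_INPUT
    #: step length of the normalized-gradient premise update; 0 freezes the
    #: premises and reduces training to the pure least-squares solve
    learning_rate: float = DEFAULT_LEARNING_RATE

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.mfs_per_input < 2:
            raise ValueError("need at least 2 membership functions per input")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


def _gbell(v: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    z = ((v - c) / a) ** 2
    return 1.0 / (1.0 + z**b)


@dataclass
class AnfisModel:
    """Trained Sugeno fuzzy system (2 inputs, one crisp output)."""

    config: AnfisConfig
    premises: np.ndarray  # shape (2, g, 3): per input, per MF, (a, b, c)
    consequents: np.ndarray  # shape (g*g, 3): per rule, (p, q, r)
    epoch_rmse: list[float] = field(default_factory=list)
    lse_warning: bool = False

    @property
    def g(self) -> int:
        return self.premises.shape[1]

    @property
    def n_rules(self) -> int:
        return self.g * self.g

    def memberships(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """mu arrays for the two inputs, each shape (n, g)."""
        mus = []
        for d in range(2):
            cols = [
                _gbell(X[:, d], *self.premises[d, j]) for j in range(self.g)
            ]
            mus.append(np.column_stack(cols))
        return mus[0], mus[1]

    def firing_strengths(self, X: np.ndarray) -> np.ndarray:
        """Normalized rule firing strengths, shape (n, g*g); rows sum to 1."""
        mu1, mu2 = self.memberships(X)
        w = (mu1[:, :, None] * mu2[:, None, :]).reshape(len(X), -1)
        total = w.sum(axis=1, keepdims=True)
        # gbell memberships are strictly positive, so total > 0 always
        return w / total

    def crisp_output(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        wbar = self.firing_strengths(X)
        f = X @ self.consequents[:, :2].T + self.consequents[:, 2]  # (n, rules)
        return np.sum(wbar * f, axis=1)

    def predict_codes(self, X: np.ndarray) -> np.ndarray:
        """Nearest class code, clamped to {1,2,3}; half-way points round down."""
        return decode_codes(self.crisp_output(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray([CODE_TO_CLASS[c] for c in self.predict_codes(X)])


def _design_matrix(wbar: np.ndarray, X: np.ndarray) -> np.ndarray:
    """LSE design: columns [wbar_r * x, wbar_r * y, wbar_r] for each rule."""
    n, rules = wbar.shape
    A = np.empty((n, rules * 3))
    A[:, 0::3] = wbar * X[:, [0]]
    A[:, 1::3] = wbar * X[:, [1]]
    A[:, 2::3] = wbar
    return A


def _solve_consequents(model: AnfisModel, X: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, float, bool]:
    wbar = model.firing_strengths(X)
    A = _design_matrix(wbar, X)
    theta, _, rank, _ = np.linalg.lstsq(A, t, rcond=None)
    degenerate = rank < A.shape[1]
    resid = A @ theta - t
    rmse = float(np.sqrt(np.mean(resid**2)))
    return theta.reshape(-1, 3), rmse, degenerate


def _premise_gradient(model: AnfisModel, X: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Analytic gradient of the summed squared error w.r.t. (a, b, c) premises."""
    g = model.g
    n = len(X)
    mu1, mu2 = model.memberships(X)
    w = (mu1[:, :, None] * mu2[:, None, :]).reshape(n, -1)
    total = w.sum(axis=1, keepdims=True)
    wbar = w / total
    f = X @ model.consequents[:, :2].T + model.consequents[:, 2]
    out = np.sum(wbar * f, axis=1)
    err = out - t  # dE/dout (up to factor 2, absorbed in the step length)
    # dout/dw_r = (f_r - out) / total
    dout_dw = (f - out[:, None]) / total  # (n, rules)
    grad = np.zeros_like(model.premises)
    rule_i, rule_j = np.divmod(np.arange(g * g), g)
    for d in range(2):
        mu_self = mu1 if d == 0 else mu2
        mu_other = mu2 if d == 0 else mu1
        idx_self = rule_i if d == 0 else rule_j
        idx_other = rule_j if d == 0 else rule_i
        for j in range(g):
            a, b, c = model.premises[d, j]
            v = X[:, d]
            z = ((v - c) / a) ** 2
            mu = mu_self[:, j]
            zb = z**b
            # dmu/dz, guarded at z == 0
            with np.errstate(divide="ignore", invalid="ignore"):
                dmu_dz = np.where(z > 0, -b * zb / z * mu**2, 0.0)
                dmu_db = np.where(z > 0, -(mu**2) * zb * np.log(np.where(z > 0, z, 1.0)), 0.0)
            dz_dc = -2.0 * (v - c) / a**2
            dz_da = -2.0 * z / a
            # dw_r/dmu_{d,j} = mu_other for rules whose d-th premise is j
            rules_j = np.nonzero(idx_self == j)[0]
            dout_dmu = np.sum(
                dout_dw[:, rules_j] * mu_other[:, idx_other[rules_j]], axis=1
            )
            common = err * dout_dmu
            grad[d, j, 0] = np.sum(common * dmu_dz * dz_da)
            grad[d, j, 1] = np.sum(common * dmu_db)
            grad[d, j, 2] = np.sum(common * dmu_dz * dz_dc)
    return grad


def train_anfis(
    features: list[FeatureVector] | tuple[np.ndarray, np.ndarray],
    targets: np.ndarray | None = None,
    config: AnfisConfig | None = None,
) -> AnfisModel:
    """Hybrid training: exact LSE consequents + backtracked gradient premises.

    ``features`` may be a list of FeatureVector (targets derived from their
    labels as codes 1/2/3) or an (X, y-codes) tuple with explicit numeric
    targets.  Premise bells start on an even grid over each input's training
    range (centres equally spaced, width a = half the centre spacing, b = 2).
    The recorded epoch RMSE is non-increasing: a premise step that would
    increase the error is halved and, if still harmful, skipped.
    """
    cfg = config or AnfisConfig()
    if isinstance(features, tuple):
        X, t = features
        X = np.asarray(X, dtype=float)
        t = np.asarray(t)
        if t.dtype.kind in "US":  # class labels -> codes 1/2/3
            t = labels_to_codes(t)
        t = t.astype(float)
    else:
        X, _ = features_to_arrays(features)
        t = labels_to_codes(np.array([f.label for f in features]))
    if targets is not None:
        t = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("ANFIS expects exactly 2 input features (lle, entropy)")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite training data")
    g = cfg.mfs_per_input
    premises = np.empty((2, g, 3))
    for d in range(2):
        lo, hi = X[:, d].min(), X[:, d].max()
        if hi == lo:
            raise ValueError(f"input {d} is constant; cannot place membership grid")
        if len(np.unique(X[:, d])) < g:
            raise ValueError(f"input {d} has fewer than {g} distinct values")
        centres = np.linspace(lo, hi, g)
        a = (centres[1] - centres[0]) / 2.0
        for j in range(g):
            premises[d, j] = (a, 2.0, centres[j])
    model = AnfisModel(config=cfg, premises=premises, consequents=np.zeros((g * g, 3)))

    theta, rmse, degenerate = _solve_consequents(model, X, t)
    model.consequents = theta
    if degenerate:
        model.lse_warning = True
        logger.warning("rank-deficient least-squares system; minimum-norm solution used")
    model.epoch_rmse.append(rmse)

    for _ in range(cfg.epochs):
        if cfg.learning_rate > 0:
            grad = _premise_gradient(model, X, t)
            norm = float(np.linalg.norm(grad))
            if norm > 0:
                # scale-aware normalized step, backtracked to keep RMSE monotone
                scale = np.maximum(np.abs(model.premises), 1e-3)
                step = cfg.learning_rate
                best = model.epoch_rmse[-1]
                old_premises = model.premises.copy()
                old_theta = model.consequents.copy()
                accepted = False
                for _try in range(8):
                    model.premises = old_premises - step * scale * (grad / norm)
                    model.premises[:, :, 0] = np.maximum(model.premises[:, :, 0], 1e-6)
                    model.premises[:, :, 1] = np.maximum(model.premises[:, :, 1], 1e-3)
                    theta, rmse, degenerate = _solve_consequents(model, X, t)
                    if rmse <= best + 1e-12:
                        model.consequents = theta
                        accepted = True
                        break
                    step /= 2.0
                if not accepted:
                    model.premises = old_premises
                    model.consequents = old_theta
                    rmse = best
        else:
            theta, rmse, degenerate = _solve_consequents(model, X, t)
            model.consequents = theta
        model.epoch_rmse.append(rmse)
    return model


def anfis_predict(model: AnfisModel, feature: FeatureVector | np.ndarray) -> dict:
    """Classify one feature vector; returns the crisp output and the label."""
    x = feature.xy if isinstance(feature, FeatureVector) else np.asarray(feature, dtype=float)
    out = float(model.crisp_output(x)[0])
    code = int(model.predict_codes(x)[0])
    return {"label": CODE_TO_CLASS[code], "crisp_output": out, "code": code}
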