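"""Three-factor neural network for ICI response prediction.

A single-hidden-layer network over (HAPS, TMB, TCR diversity):

    score = sigma( b_out + w_out * sigma( b_h + sum_i w_i * x_i ) )

with one logistic hidden unit and a logistic output, trained by resilient
backpropagation (RPROP, sign-based per-weight step sizes) on the
sum-of-squared-errors loss. The architecture is deliberately tiny: with
three inputs and one hidden unit the model has six free parameters, which
bounds overfitting on the small cohorts it is meant for.

A frozen "reference model" ships with the package: the published
coefficient set (hidden intercept 1.9214; input weights 1.54006, 1.4383,
2.46875; output bias -0.42557 and hidden-to-output weight -1.76532;
decision threshold 0.436). It is used for forward-pass regression checks
and as a worked example, not as retrainable ground truth — reading the two
printed output-layer numbers as (bias, hidden-to-output weight) is this
package's documented interpretation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import DataError

FEATURES = ("haps", "tmb", "tcr_diversity")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class NNModel:
    """Weights, standardization parameters and decision threshold."""

    feature_names: tuple
    means: np.ndarray
    scales: np.ndarray
    w_in: np.ndarray  # (3,) input -> hidden
    b_hidden: float
    w_out: float  # hidden -> output
    b_out: float
    threshold: float | None = None
    seed: int | None = None
    n_iter: int = 0
    final_sse: float = float("nan")
    converged: bool = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Forward pass on already-standardized inputs, shape (n, 3)."""
        h = _sigmoid(self.b_hidden + x @ self.w_in)
        return _sigmoid(self.b_out + self.w_out * h)

    def to_json(self) -> str:
        payload = {
            "architecture": "3-1-1 logistic",
            "feature_names": list(self.feature_names),
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "w_in": self.w_in.tolist(),
            "b_hidden": self.b_hidden,
            "w_out": self.w_out,
            "b_out": self.b_out,
            "threshold": self.threshold,
            "seed": self.seed,
            "training_log": {
                "n_iter": self.n_iter,
                "final_sse": None if np.isnan(self.final_sse) else self.final_sse,
                "converged": self.converged,
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NNModel":
        d = json.loads(text)
        log = d.get("training_log", {})
        return cls(
            feature_names=tuple(d["feature_names"]),
            means=np.asarray(d["means"], dtype=float),
            scales=np.asarray(d["scales"], dtype=float),
            w_in=np.asarray(d["w_in"], dtype=float),
            b_hidden=float(d["b_hidden"]),
            w_out=float(d["w_out"]),
            b_out=float(d["b_out"]),
            threshold=d.get("threshold"),
            seed=d.get("seed"),
            n_iter=int(log.get("n_iter", 0)),
            final_sse=float(log["final_sse"]) if log.get("final_sse") is not None
            else float("nan"),
            converged=bool(log.get("converged", False)),
        )


def reference_model() -> NNModel:
    """The frozen published coefficient set (identity standardization)."""
    return NNModel(
        feature_names=FEATURES,
        means=np.zeros(3),
        scales=np.ones(3),
        w_in=np.array([1.54006, 1.4383, 2.46875]),
        b_hidden=1.9214,
        w_out=-1.76532,
        b_out=-0.42557,
        threshold=0.436,
    )


def _as_matrix(features, feature_names=FEATURES) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [f for f in feature_names if f not in features.columns]
        if missing:
            raise DataError(f"feature columns missing: {missing}")
        x = features.loc[:, list(feature_names)].to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x.reshape(1, -1)
        if x.shape[1] != len(feature_names):
            raise DataError(
                f"expected {len(feature_names)} feature columns, got {x.shape[1]}"
            )
    if not np.isfinite(x).all():
        raise DataError("features contain non-finite values")
    return x


@dataclass(frozen=True)
class Standardizer:
    feature_names: tuple
    means: np.ndarray
    scales: np.ndarray

    def transform(self, features) -> np.ndarray:
        x = _as_matrix(features, self.feature_names)
        return (x - self.means) / self.scales


def standardize(features, feature_names=FEATURES) -> tuple[np.ndarray, Standardizer]:
    """Fit per-feature z-scoring (population SD) and transform the input."""
    x = _as_matrix(features, feature_names)
    if x.shape[0] < 2:
        raise DataError("standardization requires >= 2 patients")
    means = x.mean(axis=0)
    scales = x.std(axis=0)
    for name, s in zip(feature_names, scales):
        if s == 0:
            raise DataError(f"feature {name!r} is constant; cannot standardize")
    st = Standardizer(tuple(feature_names), means, scales)
    return st.transform(features), st


def _sse_and_grad(theta: np.ndarray, x: np.ndarray, y: np.ndarray):
    """Loss 0.5 * sum (yhat - y)^2 and its gradient for the 3-1-1 network.

    theta = [w_in(3), b_hidden, w_out, b_out].
    """
    w_in, b_h, w_out, b_out = theta[:3], theta[3], theta[4], theta[5]
    h = _sigmoid(b_h + x @ w_in)
    yhat = _sigmoid(b_out + w_out * h)
    err = yhat - y
    sse = 0.5 * float(err @ err)
    d_out = err * yhat * (1 - yhat)  # dL/d(output preactivation)
    g_bout = d_out.sum()
    g_wout = float(d_out @ h)
    d_h = d_out * w_out * h * (1 - h)
    g_bh = d_h.sum()
    g_win = x.T @ d_h
    return sse, np.concatenate([g_win, [g_bh, g_wout, g_bout]])


def train(
    features,
    labels,
    seed: int,
    max_iter: int = 20,
    tol: float = 0.01,
    feature_names=FEATURES,
) -> NNModel:
    """Train the 3-1-1 logistic network with RPROP on the SSE loss.

    Inputs are z-scored with parameters stored on the model. Training stops
    when the absolute SSE change falls below ``tol`` or after ``max_iter``
    RPROP iterations (full-batch updates). Initialization is drawn from the
    seeded generator, so equal seeds give identical models.
    """
    x_std, st = standardize(features, feature_names)
    y = np.asarray(labels, dtype=float).ravel()
    if y.size != x_std.shape[0]:
        raise DataError("labels and features disagree in length")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise DataError(
            f"labels must contain both classes coded 0/1, got {classes.tolist()}"
        )
    if y.size < 10:
        raise DataError(f"training requires >= 10 patients, got {y.size}")

    rng = np.random.default_rng(seed)
    theta = rng.normal(0.0, 0.5, size=6)

    # RPROP- : per-parameter step sizes adapted from gradient sign agreement
    delta = np.full(6, 0.1)
    delta_min, delta_max = 1e-6, 50.0
    eta_plus, eta_minus = 1.2, 0.5
    prev_grad = np.zeros(6)
    prev_sse = np.inf
    sse = np.nan
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sse, grad = _sse_and_grad(theta, x_std, y)
        if abs(prev_sse - sse) < tol:
            converged = True
            break
        sign_change = prev_grad * grad
        delta = np.where(sign_change > 0, np.minimum(delta * eta_plus, delta_max),
                         delta)
        shrink = sign_change < 0
        delta = np.where(shrink, np.maximum(delta * eta_minus, delta_min), delta)
        grad_eff = np.where(shrink, 0.0, grad)
        theta = theta - np.sign(grad_eff) * delta
        prev_grad = grad_eff
        prev_sse = sse
    final_sse, _ = _sse_and_grad(theta, x_std, y)
    return NNModel(
        feature_names=tuple(feature_names),
        means=st.means,
        scales=st.scales,
        w_in=theta[:3].copy(),
        b_hidden=float(theta[3]),
        w_out=float(theta[4]),
        b_out=float(theta[5]),
        threshold=None,
        seed=seed,
        n_iter=it,
        final_sse=final_sse,
        converged=converged,
    )


def predict(model: NNModel, features) -> np.ndarray:
    """Response score in (0, 1) per patient; deterministic forward pass."""
    x = _as_matrix(features, model.feature_names)
    x_std = (x - model.means) / model.scales
    return model.forward(x_std)


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden_j: np.ndarray
    threshold: float
    j_max: float


def youden_threshold(scores, labels) -> ROCResult:
    """Decision threshold maximizing Youden's J = sens + spec - 1.

    J is evaluated at every observed score (classification rule:
    score >= threshold is called positive); ties in J resolve to the lower
    threshold.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if s.size != y.size:
        raise DataError("scores and labels disagree in length")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise DataError(
            f"labels must contain both classes coded 0/1, got {classes.tolist()}"
        )
    grid = np.unique(s)
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    sens = np.array([np.sum((s >= t) & (y == 1)) / n_pos for t in grid])
    spec = np.array([np.sum((s < t) & (y == 0)) / n_neg for t in grid])
    j = sens + spec - 1
    # lowest threshold among (float-tolerant) ties for the maximum
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    return ROCResult(
        thresholds=grid,
        sensitivity=sens,
        specificity=spec,
        youden_j=j,
        threshold=float(grid[best]),
        j_max=float(j[best]),
    )


def set_threshold(model: NNModel, features, labels) -> NNModel:
    """Attach the Youden-optimal threshold of the given set to the model."""
    roc = youden_threshold(predict(model, features), labels)
    return replace(model, threshold=roc.threshold)


def rank_importance(
    model: NNModel,
    features,
    labels,
    n_permutations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance: mean AUC drop when one feature is shuffled.

    Returns a DataFrame (feature, importance) sorted by importance
    descending, ties broken lexicographically by feature name.
    """
    if n_permutations < 1:
        raise DataError(f"n_permutations must be >= 1, got {n_permutations}")
    x = _as_matrix(features, model.feature_names)
    y = np.asarray(labels, dtype=float).ravel()
    base_auc = roc_auc_score(y, predict(model, x))
    rng = np.random.default_rng(seed)
    rows = []
    for k, name in enumerate(model.feature_names):
        drops = np.empty(n_permutations)
        for rep in range(n_permutations):
            xp = x.copy()
            xp[:, k] = rng.permutation(xp[:, k])
            drops[rep] = base_auc - roc_auc_score(y, predict(model, xp))
        rows.append({"feature": name, "importance": float(drops.mean())})
    out = pd.DataFrame(rows).sort_values(
        ["importance", "feature"], ascending=[False, True]
    )
    return out.reset_index(drop=True)
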