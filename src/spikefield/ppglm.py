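"""Point-process GLM: design assembly, likelihood, fitting, introspection.

The model treats each 1 ms bin as a Bernoulli trial whose success
probability is lambda_t * Delta, with the conditional intensity lambda_t
(spikes/s) log-linear in the covariates:

    ln(lambda_t) = mu + A . X_t

Fitting maximizes the per-sample-normalized log-likelihood with an L2
penalty on A (mu unpenalized):

    (1/T) sum_t [ Y_t ln(lambda_t Delta) - lambda_t Delta ] - alpha ||A||^2

All covariates are z-scored before fitting so the penalty treats them
symmetrically; the z-scoring statistics travel with the fitted model so that
held-out data is always scored with training statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import _solver
from .core import DELTA_S, BinnedSpikeTrain, FeatureBlock

logger = logging.getLogger(__name__)

LOG_DELTA = float(np.log(DELTA_S))


@dataclass
class FeatureMatrix:
    """Design matrix on the 1 ms grid with labels, group tags and z-stats."""

    X: np.ndarray
    labels: list
    groups: list
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X))
        if len(self.labels) != self.X.shape[1] or len(self.groups) != self.X.shape[1]:
            raise ValueError("labels/groups must match column count")
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise ValueError("design matrix contains non-finite entries")

    @property
    def T(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def is_scored(self) -> bool:
        return self.mean is not None


def assemble_design(
    blocks: list[FeatureBlock],
    stats_from: "FeatureMatrix | None" = None,
    *,
    min_sd: float = 1e-12,
) -> FeatureMatrix:
    """Concatenate feature blocks into a z-scored design matrix.

    With ``stats_from`` given (a training-set design), columns are selected
    and scaled using the *training* statistics — the correct treatment of
    held-out data.  Otherwise each column is z-scored with its own mean/sd
    and zero-variance columns are dropped with a logged warning.
    """
    if blocks:
        n_rows = {b.n_rows for b in blocks}
        if len(n_rows) != 1:
            raise ValueError("feature blocks do not share a time base")
        raw = np.hstack([b.values for b in blocks]) if blocks else None
        labels = [lb for b in blocks for lb in b.labels]
        groups = [b.group for b in blocks for _ in b.labels]
    else:
        raw = np.empty((0, 0))
        labels, groups = [], []

    if stats_from is not None:
        pos = {lb: i for i, lb in enumerate(labels)}
        try:
            sel = [pos[lb] for lb in stats_from.labels]
        except KeyError as exc:
            raise ValueError(f"label {exc} missing from blocks") from exc
        Z = (raw[:, sel] - stats_from.mean) / stats_from.sd
        return FeatureMatrix(
            Z, list(stats_from.labels), list(stats_from.groups),
            stats_from.mean.copy(), stats_from.sd.copy(),
        )

    if raw.shape[1] == 0:
        return FeatureMatrix(raw.reshape(raw.shape[0], 0), [], [],
                             np.empty(0), np.empty(0))
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)
    keep = sd > min_sd
    if not keep.all():
        dropped = [lb for lb, k in zip(labels, keep) if not k]
        logger.warning("dropping zero-variance columns: %s", dropped)
    Z = (raw[:, keep] - mean[keep]) / sd[keep]
    return FeatureMatrix(
        Z,
        [lb for lb, k in zip(labels, keep) if k],
        [g for g, k in zip(groups, keep) if k],
        mean[keep],
        sd[keep],
    )


@dataclass
class PPGLMModel:
    """Fitted point-process GLM: baseline mu (log spikes/s) and weights A."""

    mu: float
    A: np.ndarray
    alpha: float
    labels: list = field(default_factory=list)
    groups: list = field(default_factory=list)
    zscore_mean: np.ndarray | None = None
    zscore_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if len(self.labels) != self.A.size:
            raise ValueError("one label per weight required")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not (np.isfinite(self.mu) and np.all(np.isfinite(self.A))):
            raise ValueError("non-finite model parameters")

    def to_json(self) -> str:
        return json.dumps(
            {
                "mu": self.mu,
                "A": self.A.tolist(),
                "alpha": self.alpha,
                "labels": list(self.labels),
                "groups": list(self.groups),
                "zscore_mean": None if self.zscore_mean is None
                else np.asarray(self.zscore_mean).tolist(),
                "zscore_sd": None if self.zscore_sd is None
                else np.asarray(self.zscore_sd).tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PPGLMModel":
        d = json.loads(text)
        return cls(
            mu=d["mu"], A=np.array(d["A"]), alpha=d["alpha"],
            labels=d["labels"], groups=d["groups"],
            zscore_mean=None if d["zscore_mean"] is None else np.array(d["zscore_mean"]),
            zscore_sd=None if d["zscore_sd"] is None else np.array(d["zscore_sd"]),
        )


def _scored_values(model: PPGLMModel, X: FeatureMatrix) -> np.ndarray:
    if list(X.labels) != list(model.labels):
        raise ValueError("feature labels do not match the model")
    if X.is_scored:
        return X.X
    if model.zscore_mean is None:
        return X.X
    return (X.X - model.zscore_mean) / model.zscore_sd


def conditional_intensity(model: PPGLMModel, X: FeatureMatrix) -> np.ndarray:
    """lambda_t = exp(mu + A . X_t) in spikes/s.

    Unscored inputs are z-scored with the model's training statistics.
    """
    Z = _scored_values(model, X)
    eta = model.mu + (Z @ model.A if model.A.size else 0.0)
    return np.exp(eta)


def _as_y(Y) -> np.ndarray:
    if isinstance(Y, BinnedSpikeTrain):
        return Y.values.astype(float)
    return np.asarray(Y, dtype=float)


def penalized_nll_and_gradient(mu, A, X, Y, alpha):
    """Negative penalized log-likelihood and its exact gradient.

    Returns (nll, grad) with grad[0] the mu component and grad[1:] aligned to
    A.  nll = -(1/T) sum[Y ln(lambda Delta) - lambda Delta] + alpha ||A||^2.
    """
    A = np.asarray(A, dtype=float)
    Xv = X.X if isinstance(X, FeatureMatrix) else np.atleast_2d(np.asarray(X, float))
    y = _as_y(Y)
    T = y.size
    if Xv.shape[0] != T:
        raise ValueError("X and Y length mismatch")
    psi = mu + LOG_DELTA + (Xv @ A if A.size else 0.0)
    lam_delta = np.exp(psi)
    if not np.all(np.isfinite(lam_delta)):
        bad = int(np.flatnonzero(~np.isfinite(lam_delta))[0])
        raise FloatingPointError(f"intensity overflow at bin {bad}")
    resid = y - lam_delta
    nll = -(np.sum(y * psi) - np.sum(lam_delta)) / T + alpha * float(A @ A)
    gmu = -resid.sum() / T
    gA = -(Xv.T @ resid) / T + 2 * alpha * A if A.size else np.empty(0)
    return nll, np.concatenate([[gmu], gA])


def fit_ppglm(
    X: FeatureMatrix | None,
    Y,
    alpha: float,
    *,
    w0: np.ndarray | None = None,
    tol: float = 1e-9,
    gtol: float = 1e-9,
    max_iter: int = 100,
) -> PPGLMModel:
    """Minimize the penalized NLL by full Newton iteration (convex, unique).

    ``X`` must be a z-scored :class:`FeatureMatrix` (an unscored one is
    scored with its own statistics first); ``X=None`` fits the
    covariate-free model whose solution is mu = ln(mean(Y)/Delta).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    y = _as_y(Y)
    if X is None or X.p == 0:
        Xv = np.empty((y.size, 0))
        labels, groups = [], []
        mean = sd = None
    else:
        if not X.is_scored:
            m = X.X.mean(axis=0)
            s = X.X.std(axis=0)
            keep = s > 1e-12
            if not keep.all():
                logger.warning(
                    "dropping zero-variance columns: %s",
                    [lb for lb, k in zip(X.labels, keep) if not k],
                )
            X = FeatureMatrix(
                (X.X[:, keep] - m[keep]) / s[keep],
                [lb for lb, k in zip(X.labels, keep) if k],
                [g for g, k in zip(X.groups, keep) if k],
                m[keep],
                s[keep],
            )
        if X.T != y.size:
            raise ValueError("X and Y length mismatch")
        Xv, labels, groups = X.X, list(X.labels), list(X.groups)
        mean, sd = X.mean, X.sd
    X1 = np.column_stack([np.ones(y.size), Xv])
    start = None
    if w0 is not None:
        start = np.concatenate([[w0[0] + LOG_DELTA], w0[1:]])
    w, info = _solver.exact_newton(
        X1, y, alpha, w0=start, tol=tol, gtol=gtol, max_iter=max_iter
    )
    if info["capped"]:
        raise RuntimeError(
            "intensity cap active at the solution; the fitted model is "
            "outside the trusted regime"
        )
    return PPGLMModel(
        mu=float(w[0]) - LOG_DELTA, A=w[1:], alpha=alpha,
        labels=labels, groups=groups, zscore_mean=mean, zscore_sd=sd,
    )


def standard_errors(model: PPGLMModel, X: FeatureMatrix, Y=None):
    """Asymptotic standard errors from the observed information matrix.

    Returns (se_mu, se_A).  The information is sum_t lambda_t Delta x x'
    evaluated at the fit (the penalty is ignored; intended for small alpha).
    """
    Z = _scored_values(model, X)
    lam_delta = conditional_intensity(model, X) * DELTA_S
    X1 = np.column_stack([np.ones(Z.shape[0]), Z])
    info = (X1 * lam_delta[:, None]).T @ X1
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return float(se[0]), se[1:]


def preferred_phase(model: PPGLMModel, band: str):
    """Preferred phase theta0 and modulation depth for a narrow band.

    The cos/sin phase-pair weights (returned to their raw, pre-z-scoring
    scale) parameterize cosine phase tuning
    a4 cos(theta0 - phase) with a4 = sqrt(w_cos^2 + w_sin^2) and
    theta0 = atan2(w_sin, w_cos).
    """
    try:
        ic = model.labels.index(f"{band}_cosph")
        isn = model.labels.index(f"{band}_sinph")
    except ValueError:
        raise ValueError(
            f"band {band!r} has no phase features in this model (broad band?)"
        ) from None
    wc, ws = model.A[ic], model.A[isn]
    if model.zscore_sd is not None:
        wc = wc / model.zscore_sd[ic]
        ws = ws / model.zscore_sd[isn]
    return float(np.arctan2(ws, wc)), float(np.hypot(wc, ws))
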