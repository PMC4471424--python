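"""Sparse Bayesian (relevance vector machine) binary classification.

The classifier is a logistic model ``p(z=1|x) = sigma(w' phi(x))`` whose
weights carry independent zero-mean Gaussian priors ``w_i ~ N(0, 1/alpha_i)``
with one precision hyperparameter per basis function. Training alternates:

1. MAP estimation of the weights for fixed ``alpha`` by iteratively
   reweighted least squares (penalized logistic regression), yielding the
   mode ``w*`` and the Laplace posterior covariance
   ``Sigma = (Phi' B Phi + diag(alpha))^{-1}``;
2. evidence (type-II maximum likelihood) updates of the precisions via the
   MacKay fixed point ``alpha_i <- gamma_i / w_i**2`` with
   ``gamma_i = 1 - alpha_i * Sigma_ii``.

Most precisions diverge, pruning their basis functions; the training points
(or features) that survive are the relevance vectors. Predictions marginalize
the weight posterior with the standard probit ("moderated") approximation
``sigma(mu / sqrt(1 + pi s^2 / 8))``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import linalg

from .errors import DegenerateModelError, NumericError, ValidationError

logger = logging.getLogger(__name__)

_CLIP = 1e-12


@dataclass
class BasisSpec:
    """Basis / kernel specification plus the statistics fitted on training data.

    ``linear`` gives the design ``[1 | standardized X]``; ``rbf`` gives
    ``[1 | K]`` with a Gaussian kernel over standardized rows, one basis
    function per training point. Zero-variance features are excluded from
    standardization with a warning.
    """

    kind: str = "linear"
    rbf_width: float = 1.0
    include_bias: bool = True
    # fitted state
    feature_means: np.ndarray | None = None
    feature_sds: np.ndarray | None = None
    kept_features: np.ndarray | None = None
    centers: np.ndarray | None = None  # standardized training rows (rbf only)

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf"):
            raise ValidationError(f"unknown basis kind {self.kind!r}")
        if self.kind == "rbf" and not self.rbf_width > 0:
            raise ValidationError("rbf_width must be positive")

    @property
    def fitted(self) -> bool:
        return self.feature_means is not None

    def fit(self, X: np.ndarray) -> "BasisSpec":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValidationError("X must be a 2-D array with at least one row")
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=0)
        kept = np.flatnonzero(sds > 0)
        if kept.size < X.shape[1]:
            dropped = sorted(set(range(X.shape[1])) - set(kept.tolist()))
            logger.warning("excluding zero-variance features at indices %s", dropped)
        self.feature_means = means
        self.feature_sds = sds
        self.kept_features = kept
        if self.kind == "rbf":
            self.centers = self._standardize(X)
        return self

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        k = self.kept_features
        return (X[:, k] - self.feature_means[k]) / self.feature_sds[k]

    def n_basis(self) -> int:
        if not self.fitted:
            raise ValidationError("basis not fitted")
        m = len(self.centers) if self.kind == "rbf" else len(self.kept_features)
        return m + int(self.include_bias)


def build_design(X: np.ndarray, basis: BasisSpec) -> np.ndarray:
    """Evaluate the design matrix for rows ``X`` under a basis.

    An unfitted basis is fitted on ``X`` first (i.e. ``X`` is treated as the
    training set); otherwise the stored training statistics are applied.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not basis.fitted:
        basis.fit(X)
    Z = basis._standardize(X)
    if basis.kind == "linear":
        cols = Z
    else:
        sq = (
            (Z**2).sum(axis=1)[:, None]
            + (basis.centers**2).sum(axis=1)[None, :]
            - 2.0 * Z @ basis.centers.T
        )
        cols = np.exp(-np.maximum(sq, 0.0) / (2.0 * basis.rbf_width**2))
    if basis.include_bias:
        return np.hstack([np.ones((len(cols), 1)), cols])
    return cols


@dataclass
class RVMConfig:
    """Optimization knobs for RVM training; all positive, all configurable."""

    alpha_init: float = 1.0
    prune_threshold: float = 1e9
    gamma_prune_tol: float = 1e-5
    outer_tol: float = 1e-3
    outer_max_iter: int = 1000
    irls_tol: float = 1e-6
    irls_max_iter: int = 100
    predictive: str = "moderated"  # or "plugin"
    jitter: float = 1e-8

    def __post_init__(self) -> None:
        for name in (
            "alpha_init", "prune_threshold", "gamma_prune_tol",
            "outer_tol", "irls_tol", "jitter",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.outer_max_iter < 1 or self.irls_max_iter < 1:
            raise ValidationError("iteration limits must be >= 1")
        if self.predictive not in ("moderated", "plugin"):
            raise ValidationError("predictive must be 'moderated' or 'plugin'")


@dataclass
class RVMModel:
    """A fitted sparse Bayesian classifier.

    ``active_cols`` indexes the surviving columns of the full design matrix;
    ``relevance_indices`` are the surviving non-bias basis functions (for an
    rbf basis: the relevance-vector training points).
    """

    basis: BasisSpec
    alpha: np.ndarray
    w_map: np.ndarray
    sigma_post: np.ndarray
    active_cols: np.ndarray
    relevance_indices: np.ndarray
    trace: list[float] = field(default_factory=list)
    config: RVMConfig = field(default_factory=RVMConfig)

    def __post_init__(self) -> None:
        if not (len(self.alpha) == len(self.w_map) == self.sigma_post.shape[0]):
            raise ValidationError("alpha, w_map and sigma_post sizes disagree")
        if np.max(np.abs(self.sigma_post - self.sigma_post.T)) > 1e-8:
            raise NumericError("posterior covariance not symmetric")
        if not (np.asarray(self.alpha) > 0).all():
            raise ValidationError("all alpha must be positive")


def sigmoid(y):
    """Logistic link, clipped to [1e-12, 1 - 1e-12] for stable log-likelihoods."""
    out = np.empty_like(y, dtype=float) if np.ndim(y) else None
    p = 0.5 * (1.0 + np.tanh(np.asarray(y, dtype=float) / 2.0))  # overflow-free
    p = np.clip(p, _CLIP, 1.0 - _CLIP)
    if out is None:
        return float(p)
    return p


def _penalized_loglik(Phi, z, alpha, w):
    y = Phi @ w
    p = sigmoid(y)
    return float(np.sum(z * np.log(p) + (1 - z) * np.log(1 - p)) - 0.5 * np.sum(alpha * w**2))


def irls_map(
    Phi: np.ndarray,
    z: np.ndarray,
    alpha: np.ndarray,
    irls_tol: float = 1e-6,
    irls_max_iter: int = 100,
    jitter: float = 1e-8,
    w0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """MAP weights and Laplace covariance for fixed precisions.

    Maximizes the Bernoulli log-likelihood minus ``0.5 * sum(alpha_i w_i^2)``
    by damped Newton iterations; returns ``(w*, Sigma)`` with
    ``Sigma = (Phi' B Phi + diag(alpha) + jitter I)^{-1}``.
    """
    Phi = np.asarray(Phi, dtype=float)
    z = np.asarray(z, dtype=float).ravel()
    alpha = np.asarray(alpha, dtype=float).ravel()
    if set(np.unique(z)) - {0.0, 1.0}:
        raise ValidationError("labels must be in {0, 1}")
    if (alpha <= 0).any():
        raise ValidationError("alpha must be strictly positive")
    n, m = Phi.shape
    w = np.zeros(m) if w0 is None else np.asarray(w0, dtype=float).copy()
    obj = _penalized_loglik(Phi, z, alpha, w)
    for it in range(irls_max_iter):
        p = sigmoid(Phi @ w)
        g = Phi.T @ (z - p) - alpha * w
        b = p * (1.0 - p)
        H = Phi.T @ (Phi * b[:, None]) + np.diag(alpha) + jitter * np.eye(m)
        try:
            step = linalg.solve(H, g, assume_a="pos")
        except linalg.LinAlgError as exc:  # pragma: no cover - jitter should prevent
            raise NumericError(f"IRLS Hessian solve failed at iteration {it}") from exc
        # Newton decrement below objective round-off: nothing left to gain
        if g @ step <= 1e-10 * (1.0 + abs(obj)):
            break
        # backtracking line search keeps the penalized likelihood finite & ascending
        t = 1.0
        tol = 1e-9 * (1.0 + abs(obj))
        for _ in range(30):
            w_new = w + t * step
            obj_new = _penalized_loglik(Phi, z, alpha, w_new)
            if np.isfinite(obj_new) and obj_new >= obj - tol:
                break
            t *= 0.5
        else:
            raise NumericError(f"IRLS objective non-finite/decreasing at iteration {it}")
        delta = float(np.max(np.abs(w_new - w)))
        w, obj = w_new, obj_new
        if not np.isfinite(obj):
            raise NumericError(f"non-finite objective at IRLS iteration {it}")
        if delta < irls_tol:
            break
    p = sigmoid(Phi @ w)
    b = p * (1.0 - p)
    H = Phi.T @ (Phi * b[:, None]) + np.diag(alpha) + jitter * np.eye(m)
    sigma = linalg.inv(H)
    sigma = 0.5 * (sigma + sigma.T)
    return w, sigma


def update_alpha(
    w_map: np.ndarray,
    sigma_post: np.ndarray,
    alpha: np.ndarray,
    prune_threshold: float = 1e9,
    gamma_tol: float = 1e-5,
) -> np.ndarray:
    """MacKay evidence fixed point ``alpha_i' = gamma_i / w_i^2``.

    ``gamma_i = 1 - alpha_i * Sigma_ii`` measures how well the data determine
    weight i; it approaches 0 as a basis function becomes irrelevant. Because
    ``gamma`` is a cancellation of nearly equal quantities, it cannot be
    resolved in double precision once ``alpha_i`` is very large, so any
    ``gamma_i < gamma_tol`` — including exact zeros and ``w_i = 0`` — forces
    pruning by returning ``10 * prune_threshold``. Negative ``gamma`` beyond
    round-off triggers a warning and is clamped to 0.
    """
    w = np.asarray(w_map, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    sii = np.diag(np.asarray(sigma_post, dtype=float))
    if not (len(w) == len(alpha) == len(sii)):
        raise ValidationError("inconsistent dimensions in update_alpha")
    gamma = 1.0 - alpha * sii
    if (gamma < -1e-6).any():
        logger.warning("negative gamma encountered (min %.3g); clamping to 0", gamma.min())
    gamma = np.maximum(gamma, 0.0)
    force = prune_threshold * 10.0
    with np.errstate(divide="ignore", invalid="ignore"):
        new = np.where(
            (w**2 > 0) & (gamma >= gamma_tol),
            gamma / np.maximum(w**2, _CLIP),
            force,
        )
    return np.minimum(new, force)


def _log_evidence(Phi, z, alpha, w, sigma, jitter):
    """Laplace approximation to the log marginal likelihood ln p(Z | X, alpha)."""
    m = len(w)
    loglik = _penalized_loglik(Phi, z, alpha, w)  # includes the prior quadratic
    log_prior_norm = 0.5 * np.sum(np.log(alpha)) - 0.5 * m * np.log(2 * np.pi)
    sign, logdet = np.linalg.slogdet(sigma + jitter * np.eye(m))
    if sign <= 0:
        raise NumericError("posterior covariance not positive definite")
    return loglik + log_prior_norm + 0.5 * m * np.log(2 * np.pi) + 0.5 * logdet


def fit_rvm(
    X: np.ndarray,
    z: np.ndarray,
    basis: BasisSpec | None = None,
    cfg: RVMConfig | None = None,
) -> RVMModel:
    """Train the RVM: alternate MAP weights and evidence updates, pruning as we go."""
    basis = basis if basis is not None else BasisSpec()
    cfg = cfg or RVMConfig()
    z = np.asarray(z, dtype=float).ravel()
    classes = set(np.unique(z))
    if classes != {0.0, 1.0}:
        raise DegenerateModelError(f"both classes required, got labels {sorted(classes)}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not basis.fitted:
        basis.fit(X)
    Phi_full = build_design(X, basis)
    m_full = Phi_full.shape[1]
    active = np.arange(m_full)
    alpha = np.full(m_full, cfg.alpha_init)
    w = np.zeros(m_full)
    trace: list[float] = []
    for it in range(cfg.outer_max_iter):
        Phi = Phi_full[:, active]
        w, sigma = irls_map(
            Phi, z, alpha, cfg.irls_tol, cfg.irls_max_iter, cfg.jitter, w0=w
        )
        ev = _log_evidence(Phi, z, alpha, w, sigma, cfg.jitter)
        if trace and ev < trace[-1] - 1e-6:
            logger.warning(
                "log evidence decreased at outer iteration %d (%.6f -> %.6f)",
                it, trace[-1], ev,
            )
        trace.append(ev)
        new_alpha = update_alpha(w, sigma, alpha, cfg.prune_threshold, cfg.gamma_prune_tol)
        keep = new_alpha < cfg.prune_threshold
        if basis.include_bias:
            # the bias is never pruned; freeze its alpha if flagged irrelevant
            bias_pos = np.flatnonzero(active == 0)
            keep[bias_pos] = True
            flagged = bias_pos[new_alpha[bias_pos] >= cfg.prune_threshold]
            new_alpha[flagged] = alpha[flagged]
        if not keep.any():
            raise DegenerateModelError("all basis functions pruned")
        delta = float(np.max(np.abs(np.log(new_alpha[keep]) - np.log(alpha[keep]))))
        active = active[keep]
        alpha = new_alpha[keep]
        w = w[keep]
        if delta < cfg.outer_tol:
            break
    Phi = Phi_full[:, active]
    w, sigma = irls_map(Phi, z, alpha, cfg.irls_tol, cfg.irls_max_iter, cfg.jitter, w0=w)
    offset = int(basis.include_bias)
    relevance = active[active >= offset] - offset
    return RVMModel(
        basis=basis,
        alpha=alpha,
        w_map=w,
        sigma_post=sigma,
        active_cols=active,
        relevance_indices=relevance,
        trace=trace,
        config=cfg,
    )


def _design_rows(m: RVMModel, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    phi = build_design(np.atleast_2d(x), m.basis)[:, m.active_cols]
    return phi, single


def predict_prob(m: RVMModel, x: np.ndarray, method: str | None = None):
    """Posterior probability of class 1 for covariate vector(s) ``x``.

    The default "moderated" output applies the probit approximation to the
    Gaussian-marginalized predictive integral: with ``mu = w*' phi(x)`` and
    ``s^2 = phi(x)' Sigma phi(x)``, returns ``sigma(mu / sqrt(1 + pi s^2/8))``.
    ``method="plugin"`` returns ``sigma(mu)``.
    """
    method = method or m.config.predictive
    phi, single = _design_rows(m, x)
    if phi.shape[1] != len(m.w_map):
        raise ValidationError("design/weight dimension mismatch")
    mu = phi @ m.w_map
    if method == "plugin":
        p = sigmoid(mu)
    else:
        s2 = np.einsum("ij,jk,ik->i", phi, m.sigma_post, phi)
        s2 = np.maximum(s2, 0.0)
        p = sigmoid(mu / np.sqrt(1.0 + np.pi * s2 / 8.0))
    return float(p[0]) if single else p


def predict_class(m: RVMModel, x: np.ndarray, cutoff: float = 0.5):
    """Hard 0/1 decision: class 1 iff the predictive probability >= cutoff."""
    if not 0 < cutoff < 1:
        raise ValidationError("cutoff must be in (0, 1)")
    p = predict_prob(m, x)
    if np.ndim(p):
        return (p >= cutoff).astype(int)
    return int(p >= cutoff)


_FORMAT_VERSION = 1


def save_rvm(m: RVMModel, path) -> None:
    """Serialize a fitted model to a structured text (JSON) file."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "basis": {
            "kind": m.basis.kind,
            "rbf_width": m.basis.rbf_width,
            "include_bias": m.basis.include_bias,
            "feature_means": m.basis.feature_means.tolist(),
            "feature_sds": m.basis.feature_sds.tolist(),
            "kept_features": m.basis.kept_features.tolist(),
            "centers": None if m.basis.centers is None else m.basis.centers.tolist(),
        },
        "alpha": m.alpha.tolist(),
        "w_map": m.w_map.tolist(),
        "sigma_post": m.sigma_post.tolist(),
        "active_cols": m.active_cols.tolist(),
        "relevance_indices": m.relevance_indices.tolist(),
        "trace": list(m.trace),
        "config": asdict(m.config),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_rvm(path) -> RVMModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValidationError(f"unsupported model format: {payload.get('format_version')}")
    b = payload["basis"]
    basis = BasisSpec(
        kind=b["kind"],
        rbf_width=b["rbf_width"],
        include_bias=b["include_bias"],
        feature_means=np.asarray(b["feature_means"], dtype=float),
        feature_sds=np.asarray(b["feature_sds"], dtype=float),
        kept_features=np.asarray(b["kept_features"], dtype=int),
        centers=None if b["centers"] is None else np.asarray(b["centers"], dtype=float),
    )
    return RVMModel(
        basis=basis,
        alpha=np.asarray(payload["alpha"], dtype=float),
        w_map=np.asarray(payload["w_map"], dtype=float),
        sigma_post=np.asarray(payload["sigma_post"], dtype=float),
        active_cols=np.asarray(payload["active_cols"], dtype=int),
        relevance_indices=np.asarray(payload["relevance_indices"], dtype=int),
        trace=list(payload["trace"]),
        config=RVMConfig(**payload["config"]),
    )
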