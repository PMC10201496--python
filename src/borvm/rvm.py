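"""Sparse Bayesian (relevance vector) classification.

The model is a kernel expansion y(x) = sum_m sum_i w_mi k_m(x, x_i) (+ bias)
with a Bernoulli-logistic likelihood and independent zero-mean Gaussian
priors of precision alpha_j on the weights. Inference follows the canonical
sparse-Bayesian-learning treatment for classification: the posterior mode of
the weights is found by IRLS/Newton iterations (Laplace approximation), and
the prior precisions are re-estimated by type-II maximum likelihood,

    gamma_j = 1 - alpha_j * Sigma_jj,    alpha_j <- gamma_j / mu_j**2,

with basis columns pruned once alpha_j exceeds a threshold. Training points
whose columns survive pruning are the relevance vectors; the fitted model is
typically far sparser than the full basis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .kernels import KernelSpec, gram_matrix

__all__ = [
    "TrainConfig",
    "RVMModel",
    "build_design",
    "fit_rvm",
    "train_rvm",
    "predict_proba",
    "fitness",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Numerical settings for RVM fitting.

    ``max_outer_iter`` bounds the alpha re-estimation loop (0 disables it,
    leaving a fixed-alpha MAP fit); ``prune_threshold`` is the alpha value
    above which a basis column is removed; ``max_basis`` caps the number of
    basis points per kernel (a seeded stratified subsample is used beyond
    it; pass None for the full basis).
    """

    max_outer_iter: int = 20
    irls_max_iter: int = 50
    alpha_init: float = 1.0
    prune_threshold: float = 1e12
    tol_log_alpha: float = 1e-6
    jitter: float = 1e-8
    max_basis: int | None = 600
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("alpha_init", "prune_threshold", "tol_log_alpha", "jitter"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.max_outer_iter < 0 or self.irls_max_iter < 1:
            raise ValueError("iteration counts out of range")


@dataclass
class RVMModel:
    """A fitted relevance vector machine.

    ``active_columns`` indexes the surviving columns of the training design
    matrix (column 0 is the bias when ``include_bias``); ``weight_mean`` and
    ``weight_cov`` are the Laplace-approximate posterior over those columns'
    weights. ``kernel_specs``/``basis_points`` are carried when the model was
    trained from raw inputs so it can rebuild design matrices at prediction.
    """

    weight_mean: np.ndarray
    weight_cov: np.ndarray
    alphas: np.ndarray
    active_columns: np.ndarray
    n_design_columns: int
    include_bias: bool
    kernel_specs: list[KernelSpec] | None = None
    basis_points: np.ndarray | None = None

    @property
    def n_relevance_vectors(self) -> int:
        active = set(self.active_columns.tolist())
        if self.include_bias:
            active.discard(0)
        return len(active)

    def to_dict(self) -> dict:
        return {
            "weight_mean": self.weight_mean.tolist(),
            "weight_cov": self.weight_cov.tolist(),
            "alphas": self.alphas.tolist(),
            "active_columns": self.active_columns.tolist(),
            "n_design_columns": int(self.n_design_columns),
            "include_bias": bool(self.include_bias),
            "kernel_specs": [k.to_dict() for k in self.kernel_specs] if self.kernel_specs else None,
            "basis_points": self.basis_points.tolist() if self.basis_points is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RVMModel":
        return cls(
            weight_mean=np.asarray(d["weight_mean"], dtype=float),
            weight_cov=np.asarray(d["weight_cov"], dtype=float),
            alphas=np.asarray(d["alphas"], dtype=float),
            active_columns=np.asarray(d["active_columns"], dtype=int),
            n_design_columns=int(d["n_design_columns"]),
            include_bias=bool(d["include_bias"]),
            kernel_specs=(
                [KernelSpec.from_dict(k) for k in d["kernel_specs"]] if d["kernel_specs"] else None
            ),
            basis_points=(
                np.asarray(d["basis_points"], dtype=float) if d["basis_points"] is not None else None
            ),
        )


def build_design(
    kernel_specs: KernelSpec | list[KernelSpec],
    X,
    basis_points,
    include_bias: bool = True,
) -> np.ndarray:
    """Stack one Gram block per kernel spec, with an optional leading bias column."""
    specs = [kernel_specs] if isinstance(kernel_specs, KernelSpec) else list(kernel_specs)
    if not specs:
        raise ValueError("at least one kernel spec required")
    basis_points = np.asarray(basis_points, dtype=float)
    if basis_points.size == 0:
        raise ValueError("basis_points must be non-empty")
    blocks = [gram_matrix(s, X, basis_points) for s in specs]
    if include_bias:
        blocks.insert(0, np.ones((blocks[0].shape[0], 1)))
    return np.hstack(blocks)


def _penalized_nll(z: np.ndarray, t: np.ndarray, w: np.ndarray, alphas: np.ndarray) -> float:
    # log(1 + e^z) - t*z, computed stably, plus the Gaussian prior term
    return float(np.logaddexp(0.0, z).sum() - t @ z + 0.5 * (alphas * w**2).sum())


def _irls(
    phi: np.ndarray,
    t: np.ndarray,
    alphas: np.ndarray,
    w0: np.ndarray,
    max_iter: int,
    jitter: float,
    grad_tol: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton iterations to the MAP weights; returns (w, posterior covariance)."""
    w = w0.copy()
    n_cols = phi.shape[1]
    eye = np.eye(n_cols)
    loss = _penalized_nll(phi @ w, t, w, alphas)
    for it in range(max_iter):
        z = phi @ w
        p = expit(z)
        g = phi.T @ (t - p) - alphas * w
        if np.abs(g).max() < grad_tol:
            break
        b = np.clip(p * (1 - p), 1e-12, None)
        H = (phi.T * b) @ phi
        H[np.diag_indices_from(H)] += alphas + jitter
        try:
            c = cho_factor(H, lower=True)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"IRLS Hessian factorization failed at iteration {it}") from exc
        step = cho_solve(c, g)
        # backtracking on the penalized negative log-likelihood
        eta = 1.0
        for _ in range(30):
            w_new = w + eta * step
            loss_new = _penalized_nll(phi @ w_new, t, w_new, alphas)
            if np.isfinite(loss_new) and loss_new <= loss + 1e-12:
                break
            eta *= 0.5
        else:
            break  # no descent possible; accept current MAP estimate
        w, loss = w_new, loss_new
        if not np.isfinite(loss):
            raise RuntimeError(f"IRLS diverged (non-finite loss) at iteration {it}")
    z = phi @ w
    p = expit(z)
    b = np.clip(p * (1 - p), 1e-12, None)
    H = (phi.T * b) @ phi
    H[np.diag_indices_from(H)] += alphas + jitter
    c = cho_factor(H, lower=True)
    sigma = cho_solve(c, eye)
    sigma = 0.5 * (sigma + sigma.T)
    return w, sigma


def fit_rvm(design: np.ndarray, labels, config: TrainConfig = TrainConfig()) -> RVMModel:
    """Fit the sparse Bayesian classifier on a pre-built design matrix.

    Alternates IRLS to the MAP weights with type-II alpha updates and
    pruning, until the largest |delta log alpha| falls below
    ``config.tol_log_alpha`` or ``config.max_outer_iter`` is reached.
    """
    phi = np.asarray(design, dtype=float)
    t = np.asarray(labels, dtype=float).ravel()
    if phi.ndim != 2 or phi.shape[0] != t.shape[0]:
        raise ValueError("design and labels have incompatible shapes")
    if not np.isfinite(phi).all():
        raise ValueError("design matrix contains non-finite values")
    classes = np.unique(t)
    if not np.isin(classes, [0.0, 1.0]).all():
        raise ValueError("labels must be binary 0/1")
    if classes.size < 2:
        raise ValueError("both classes must be present in the labels")

    n_cols = phi.shape[1]
    active = np.arange(n_cols)
    alphas = np.full(n_cols, config.alpha_init, dtype=float)
    w = np.zeros(n_cols)

    for _ in range(config.max_outer_iter):
        w, sigma = _irls(phi[:, active], t, alphas[active], w, config.irls_max_iter, config.jitter)
        gamma = 1.0 - alphas[active] * np.diag(sigma)
        gamma = np.clip(gamma, 1e-12, None)
        with np.errstate(divide="ignore"):
            new_alphas = np.where(w**2 > 0, gamma / w**2, np.inf)
        keep = new_alphas < config.prune_threshold
        finite = np.isfinite(new_alphas) & (alphas[active] > 0)
        delta = (
            np.abs(np.log(new_alphas[finite]) - np.log(alphas[active][finite])).max()
            if finite.any()
            else np.inf
        )
        alphas[active] = new_alphas
        active = active[keep]
        w = w[keep]
        if active.size == 0:
            log.debug("all basis columns pruned")
            break
        if delta < config.tol_log_alpha:
            break

    if active.size > 0:
        w, sigma = _irls(phi[:, active], t, alphas[active], w, config.irls_max_iter, config.jitter)
    else:
        w = np.zeros(0)
        sigma = np.zeros((0, 0))

    return RVMModel(
        weight_mean=w,
        weight_cov=sigma,
        alphas=alphas[active],
        active_columns=active,
        n_design_columns=n_cols,
        include_bias=False,
    )


def _stratified_subsample(X: np.ndarray, y: np.ndarray, size: int, seed: int) -> np.ndarray:
    """Indices of a seeded per-class proportional subsample of total ``size``."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    quota = np.floor(counts / counts.sum() * size).astype(int)
    rem = size - quota.sum()
    frac = counts / counts.sum() * size - quota
    for k in np.argsort(-frac, kind="stable")[:rem]:
        quota[k] += 1
    picks = []
    for cls, q in zip(classes, quota):
        idx = np.flatnonzero(y == cls)
        picks.append(rng.choice(idx, size=min(q, idx.size), replace=False))
    return np.sort(np.concatenate(picks))


def train_rvm(
    X,
    y,
    kernel_specs: KernelSpec | list[KernelSpec],
    config: TrainConfig = TrainConfig(),
    include_bias: bool = True,
) -> RVMModel:
    """Fit an RVM from raw inputs: pick basis points, build the design, fit.

    When the training set exceeds ``config.max_basis`` the basis is a seeded
    stratified subsample; the returned model carries the kernel specs and
    basis points needed to predict on new inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    specs = [kernel_specs] if isinstance(kernel_specs, KernelSpec) else list(kernel_specs)
    if config.max_basis is not None and X.shape[0] > config.max_basis:
        idx = _stratified_subsample(X, y, config.max_basis, config.rng_seed)
    else:
        idx = np.arange(X.shape[0])
    basis = X[idx]
    design = build_design(specs, X, basis, include_bias=include_bias)
    model = fit_rvm(design, y, config)
    model.include_bias = include_bias
    model.kernel_specs = specs
    model.basis_points = basis
    return model


def predict_proba(model: RVMModel, X) -> np.ndarray:
    """Posterior-mode probability of the positive class for each row of X.

    ``X`` is raw input when the model carries kernel specs and basis points,
    otherwise a pre-built design matrix with the training column count.
    """
    if model.kernel_specs is not None and model.basis_points is not None:
        design = build_design(model.kernel_specs, X, model.basis_points, model.include_bias)
    else:
        design = np.asarray(X, dtype=float)
    if design.shape[1] != model.n_design_columns:
        raise ValueError(
            f"dimension mismatch: design has {design.shape[1]} columns, "
            f"model expects {model.n_design_columns}"
        )
    if model.active_columns.size == 0:
        return np.full(design.shape[0], 0.5)
    return expit(design[:, model.active_columns] @ model.weight_mean)


def predict(model: RVMModel, X) -> np.ndarray:
    """Hard labels at the fixed 0.5 threshold."""
    return (predict_proba(model, X) >= 0.5).astype(int)


def fitness(
    kernel_specs: KernelSpec | list[KernelSpec],
    X,
    y,
    cv_folds: int = 5,
    config: TrainConfig = TrainConfig(),
    include_bias: bool = True,
) -> float:
    """Stratified k-fold cross-validated misclassification rate in [0, 1].

    This is the objective the Bayesian-optimization loop minimizes; it sees
    only the training partition of an experiment.
    """
    if cv_folds < 2:
        raise ValueError("cv_folds must be at least 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=config.rng_seed)
    errors = 0
    total = 0
    for tr, te in skf.split(X, y):
        if np.unique(y[tr]).size < 2:
            raise ValueError("cross-validation fold contains a single class")
        model = train_rvm(X[tr], y[tr], kernel_specs, config, include_bias)
        pred = (predict_proba(model, X[te]) >= 0.5).astype(int)
        errors += int((pred != y[te]).sum())
        total += te.size
    return errors / total
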