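"""Gaussian-process Bayesian optimization with expected improvement.

Minimizes an expensive black-box objective (here the cross-validated
classification error of an RVM configuration) over a mixed search space:
a categorical kernel family plus continuous/integer hyperparameters. A GP
surrogate models the objective from the history H = {(x_n, y_n)}; the next
configuration maximizes the expected improvement over the incumbent
y* = min y_n,

    EI(x) = (y* - mu) Phi(z) + sigma phi(z),   z = (y* - mu) / sigma,

evaluated over a seeded random candidate set (robust in mixed spaces). The
surrogate covariance is Matern-5/2 with per-dimension length-scales over the
continuous block times an exponential overlap term over the one-hot
categorical block; hyperparameters are set by marginal-likelihood
maximization with restarts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .kernels import KERNEL_FAMILIES, KernelSpec

__all__ = [
    "ContinuousDim",
    "IntegerDim",
    "SearchSpace",
    "kernel_search_space",
    "config_to_kernel_spec",
    "GPPosterior",
    "fit_surrogate",
    "expected_improvement",
    "propose_next",
    "BOConfig",
    "BOResult",
    "optimize",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContinuousDim:
    low: float
    high: float
    scale: str = "linear"  # or "log": sampled log-uniformly, encoded as log10

    def __post_init__(self):
        if not (np.isfinite(self.low) and np.isfinite(self.high) and self.low < self.high):
            raise ValueError(f"bounds must be finite with low < high, got [{self.low}, {self.high}]")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "log" and self.low <= 0:
            raise ValueError("log-scaled dimension requires positive bounds")


@dataclass(frozen=True)
class IntegerDim:
    low: int
    high: int

    def __post_init__(self):
        if self.low >= self.high:
            raise ValueError("integer dimension requires low < high")


@dataclass(frozen=True)
class SearchSpace:
    """A mixed categorical / continuous / integer search domain.

    Configurations are plain dicts mapping dimension names to values.
    ``encode`` maps a configuration to a numeric vector (one-hot categories,
    continuous and integer dimensions rescaled to [0, 1], log-scaled
    dimensions through log10 first); ``decode`` inverts it.
    """

    continuous: dict[str, ContinuousDim] = field(default_factory=dict)
    integer: dict[str, IntegerDim] = field(default_factory=dict)
    categorical: dict[str, list] = field(default_factory=dict)

    @property
    def n_categorical_dims(self) -> int:
        return sum(len(v) for v in self.categorical.values())

    @property
    def n_dims(self) -> int:
        return self.n_categorical_dims + len(self.continuous) + len(self.integer)

    def sample(self, rng: np.random.Generator) -> dict:
        cfg = {}
        for name, choices in self.categorical.items():
            cfg[name] = choices[rng.integers(len(choices))]
        for name, dim in self.continuous.items():
            if dim.scale == "log":
                cfg[name] = float(10 ** rng.uniform(np.log10(dim.low), np.log10(dim.high)))
            else:
                cfg[name] = float(rng.uniform(dim.low, dim.high))
        for name, dim in self.integer.items():
            cfg[name] = int(rng.integers(dim.low, dim.high + 1))
        return cfg

    def encode(self, cfg: dict) -> np.ndarray:
        parts = []
        for name, choices in self.categorical.items():
            onehot = np.zeros(len(choices))
            onehot[choices.index(cfg[name])] = 1.0
            parts.append(onehot)
        for name, dim in self.continuous.items():
            if dim.scale == "log":
                lo, hi = np.log10(dim.low), np.log10(dim.high)
                parts.append([(np.log10(cfg[name]) - lo) / (hi - lo)])
            else:
                parts.append([(cfg[name] - dim.low) / (dim.high - dim.low)])
        for name, dim in self.integer.items():
            parts.append([(cfg[name] - dim.low) / (dim.high - dim.low)])
        return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])

    def decode(self, x: np.ndarray) -> dict:
        cfg = {}
        pos = 0
        for name, choices in self.categorical.items():
            k = len(choices)
            cfg[name] = choices[int(np.argmax(x[pos : pos + k]))]
            pos += k
        for name, dim in self.continuous.items():
            if dim.scale == "log":
                lo, hi = np.log10(dim.low), np.log10(dim.high)
                cfg[name] = float(10 ** (lo + x[pos] * (hi - lo)))
            else:
                cfg[name] = float(dim.low + x[pos] * (dim.high - dim.low))
            pos += 1
        for name, dim in self.integer.items():
            cfg[name] = int(round(dim.low + x[pos] * (dim.high - dim.low)))
            pos += 1
        return cfg

    def categorical_mask(self) -> np.ndarray:
        """Boolean mask over encoded dimensions marking the one-hot block."""
        mask = np.zeros(self.n_dims, dtype=bool)
        mask[: self.n_categorical_dims] = True
        return mask


def kernel_search_space(
    gamma_bounds: tuple[float, float] = (1e-3, 1e3),
    coef0_bounds: tuple[float, float] = (-5.0, 5.0),
    degree_bounds: tuple[int, int] = (1, 5),
) -> SearchSpace:
    """The default BO domain: kernel family plus its hyperparameters.

    gamma is searched log-uniformly (its parameterization convention is
    absorbed by the log-scale search); coef0 and degree only act for the
    polynomial/sigmoid families but are carried for every configuration.
    """
    return SearchSpace(
        continuous={
            "gamma": ContinuousDim(*gamma_bounds, scale="log"),
            "coef0": ContinuousDim(*coef0_bounds, scale="linear"),
        },
        integer={"degree": IntegerDim(*degree_bounds)},
        categorical={"family": list(KERNEL_FAMILIES)},
    )


def config_to_kernel_spec(cfg: dict) -> KernelSpec:
    return KernelSpec(
        family=cfg["family"],
        gamma=float(cfg["gamma"]),
        coef0=float(cfg.get("coef0", 0.0)),
        degree=int(cfg.get("degree", 3)),
    )


# ----------------------------------------------------------------------------
# Gaussian-process surrogate


def _matern52(r: np.ndarray) -> np.ndarray:
    s = np.sqrt(5.0) * r
    return (1.0 + s + s**2 / 3.0) * np.exp(-s)


class GPPosterior:
    """GP surrogate over the encoded search space.

    Covariance: amp^2 * Matern52(scaled distance over non-categorical dims)
    * exp(-theta * [categories differ]) + noise on the diagonal. Length
    scales, amplitude, overlap strength and noise are fitted by maximizing
    the log marginal likelihood (L-BFGS-B, seeded restarts). A degenerate
    history (all inputs identical) falls back to the prior with a warning.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, cat_mask: np.ndarray, seed: int = 0,
                 n_restarts: int = 2, noise_floor: float = 1e-6):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.cat_mask = np.asarray(cat_mask, dtype=bool)
        self.noise_floor = noise_floor
        self.y_mean = float(self.y.mean())
        self.y_std = float(self.y.std())
        if self.y_std == 0:
            self.y_std = 1.0
        self._yn = (self.y - self.y_mean) / self.y_std
        self.n_cont = int((~self.cat_mask).sum())
        self.degenerate = len(self.X) < 2 or np.allclose(self.X, self.X[0])
        if self.degenerate:
            warnings.warn("degenerate BO history: surrogate falls back to the prior")
            self.theta = None
            return
        self._fit(seed, n_restarts)

    # hyperparameter vector: [log ell_1..ell_ncont, log theta_cat, log amp, log noise]
    def _kernel(self, params: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        ells = np.exp(params[: self.n_cont])
        theta_cat = np.exp(params[self.n_cont]) if self.cat_mask.any() else 0.0
        amp2 = np.exp(2 * params[-2])
        Ac, Bc = A[:, ~self.cat_mask] / ells, B[:, ~self.cat_mask] / ells
        d2 = ((Ac[:, None, :] - Bc[None, :, :]) ** 2).sum(axis=-1)
        k = amp2 * _matern52(np.sqrt(np.maximum(d2, 0.0)))
        if self.cat_mask.any():
            ha, hb = A[:, self.cat_mask], B[:, self.cat_mask]
            mismatch = 0.5 * np.abs(ha[:, None, :] - hb[None, :, :]).sum(axis=-1)
            k *= np.exp(-theta_cat * mismatch)
        return k

    def _nll(self, params: np.ndarray) -> float:
        K = self._kernel(params, self.X, self.X)
        noise = np.exp(2 * params[-1]) + self.noise_floor
        K[np.diag_indices_from(K)] += noise
        try:
            L = np.linalg.cholesky(K)
        except np.linalg.LinAlgError:
            return 1e10
        alpha = np.linalg.solve(L.T, np.linalg.solve(L, self._yn))
        return float(0.5 * self._yn @ alpha + np.log(np.diag(L)).sum())

    def _fit(self, seed: int, n_restarts: int) -> None:
        rng = np.random.default_rng(seed)
        n_par = self.n_cont + (1 if self.cat_mask.any() else 0) + 2
        # ordering used by _kernel: lengthscales, [theta_cat], amp, noise
        best, best_val = None, np.inf
        starts = [np.concatenate([np.zeros(n_par - 2), [0.0, np.log(0.1)]])]
        starts += [rng.uniform(-2, 1, size=n_par) for _ in range(n_restarts)]
        for x0 in starts:
            res = minimize(self._nll, x0, method="L-BFGS-B",
                           bounds=[(-5, 5)] * n_par, options={"maxiter": 100})
            if res.fun < best_val:
                best, best_val = res.x, res.fun
        self.theta = best
        K = self._kernel(best, self.X, self.X)
        K[np.diag_indices_from(K)] += np.exp(2 * best[-1]) + self.noise_floor
        self._L = np.linalg.cholesky(K)
        self._alpha = np.linalg.solve(self._L.T, np.linalg.solve(self._L, self._yn))

    def predict(self, Xq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictive mean and standard deviation at encoded query points."""
        Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
        if self.degenerate:
            mu = np.full(len(Xq), self.y_mean)
            sigma = np.full(len(Xq), self.y_std if len(self.y) > 1 else 1.0)
            return mu, sigma
        Ks = self._kernel(self.theta, Xq, self.X)
        mu = Ks @ self._alpha
        v = np.linalg.solve(self._L, Ks.T)
        amp2 = np.exp(2 * self.theta[-2])
        var = amp2 - (v**2).sum(axis=0)
        sigma = np.sqrt(np.clip(var, 0.0, None))
        return self.y_mean + self.y_std * mu, self.y_std * sigma


def fit_surrogate(history, space: SearchSpace, seed: int = 0) -> GPPosterior:
    """Fit the GP surrogate to evaluated configurations.

    ``history`` is a sequence of (config dict, objective) pairs with at
    least two finite observations.
    """
    configs = [h[0] for h in history]
    ys = np.asarray([h[1] for h in history], dtype=float)
    finite = np.isfinite(ys)
    if finite.sum() < 2:
        raise ValueError("surrogate requires at least 2 finite observations")
    X = np.array([space.encode(c) for c, ok in zip(configs, finite) if ok])
    return GPPosterior(X, ys[finite], space.categorical_mask(), seed=seed)


def expected_improvement(mu, sigma, y_star: float) -> np.ndarray:
    """Closed-form EI for minimization; total (handles sigma = 0)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if (sigma < 0).any():
        raise ValueError("sigma must be non-negative")
    improve = y_star - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, improve / np.where(sigma > 0, sigma, 1.0), 0.0)
        ei = np.where(
            sigma > 0,
            improve * norm.cdf(z) + sigma * norm.pdf(z),
            np.maximum(improve, 0.0),
        )
    return np.maximum(ei, 0.0)


def propose_next(
    posterior: GPPosterior,
    space: SearchSpace,
    rng: np.random.Generator,
    n_candidates: int = 2048,
    y_star: float | None = None,
) -> dict:
    """EI-maximizing configuration over a seeded random candidate set.

    Ties are broken by first occurrence, so the proposal is deterministic
    given the rng state.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be at least 1")
    candidates = [space.sample(rng) for _ in range(n_candidates)]
    X = np.array([space.encode(c) for c in candidates])
    mu, sigma = posterior.predict(X)
    if y_star is None:
        y_star = float(posterior.y.min())
    ei = expected_improvement(mu, sigma, y_star)
    return candidates[int(np.argmax(ei))]


@dataclass(frozen=True)
class BOConfig:
    """Budget and seeding for the optimization loop.

    ``max_iter`` is the total number of objective evaluations, the first
    ``n_init`` of which are random; the loop also stops as soon as an
    observed objective falls to ``target_fitness`` or below.
    """

    n_init: int = 8
    max_iter: int = 40
    n_candidates: int = 2048
    target_fitness: float | None = None
    seed: int = 0
    failure_penalty: float = 0.1
    use_ei: bool = True  # False = pure random search baseline

    def __post_init__(self):
        if self.max_iter < 1 or self.n_init < 1:
            raise ValueError("max_iter and n_init must be at least 1")


@dataclass
class BOResult:
    """History, best configuration and best-so-far trace of a BO run."""

    history: list  # (config, objective, failed) triples
    best_config: dict
    best_objective: float
    trace: list[float]
    termination_reason: str

    def to_dict(self) -> dict:
        return {
            "history": [
                {"config": c, "objective": float(y), "failed": bool(f)}
                for c, y, f in self.history
            ],
            "best_config": self.best_config,
            "best_objective": float(self.best_objective),
            "trace": [float(v) for v in self.trace],
            "termination_reason": self.termination_reason,
        }


def optimize(objective, space: SearchSpace, config: BOConfig = BOConfig()) -> BOResult:
    """Run the BO loop: random initialization, then surrogate + EI proposals.

    ``objective`` maps a configuration dict to a scalar to minimize. A
    configuration whose evaluation raises is recorded as failed with
    objective worst-observed + ``failure_penalty``. The returned trace of
    best-so-far objectives is non-increasing by construction.
    """
    ss = np.random.SeedSequence(config.seed)
    seed_sample, seed_gp = ss.spawn(2)
    rng = np.random.default_rng(seed_sample)
    gp_seed = int(seed_gp.generate_state(1)[0] % (2**31))

    history: list[tuple[dict, float, bool]] = []
    trace: list[float] = []
    termination = "max_iter"

    def record(cfg: dict) -> None:
        try:
            y = float(objective(cfg))
            failed = False
        except Exception as exc:  # noqa: BLE001 - failed configs are penalized, not fatal
            ok = [h[1] for h in history if not h[2]]
            y = (max(ok) if ok else 1.0) + config.failure_penalty
            failed = True
            log.warning("objective failed for %s: %s", cfg, exc)
        history.append((cfg, y, failed))
        best = min(h[1] for h in history)
        trace.append(best)
        log.info("BO evaluation %d: %s -> %.4f (best %.4f)", len(history), cfg, y, best)

    n_init = min(config.n_init, config.max_iter)
    for _ in range(n_init):
        record(space.sample(rng))
        if config.target_fitness is not None and trace[-1] <= config.target_fitness:
            termination = "target_fitness"
            break

    while termination == "max_iter" and len(history) < config.max_iter:
        if config.use_ei:
            try:
                posterior = fit_surrogate(history, space, seed=gp_seed)
                cfg = propose_next(
                    posterior, space, rng, config.n_candidates,
                    y_star=min(h[1] for h in history),
                )
            except ValueError:
                cfg = space.sample(rng)
        else:
            cfg = space.sample(rng)
        record(cfg)
        if config.target_fitness is not None and trace[-1] <= config.target_fitness:
            termination = "target_fitness"

    best_idx = int(np.argmin([h[1] for h in history]))
    return BOResult(
        history=history,
        best_config=history[best_idx][0],
        best_objective=history[best_idx][1],
        trace=trace,
        termination_reason=termination,
    )
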