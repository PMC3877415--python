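"""BIC, BMA weights, Bayes factors, mixed predictive sampling, and
posterior-prediction-interval coverage.

The BIC uses the number of *uncensored* observations as its sample size:
``BIC = -2 * max_loglik + d * log(n_events)``.  Model weights follow the
BIC approximation of the posterior model probability,
``w_s ∝ exp(-BIC_s / 2) * p(S = s)``, computed after subtracting the
minimum BIC for overflow safety (a shift that cancels in the
normalization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from survbma.mcmc import PosteriorChain

__all__ = [
    "ModelFitSummary",
    "BMAResult",
    "compute_bic",
    "max_loglik_estimate",
    "fit_summary",
    "bma_weights",
    "bma_from_summaries",
    "bayes_factor",
    "bma_predictive",
    "coverage",
    "predictive_intervals",
]

logger = logging.getLogger(__name__)


def compute_bic(max_loglik: float, d_s: int, n_events: int) -> float:
    """-2 * max_loglik + d_s * log(n_events); smaller is better."""
    if n_events < 1:
        raise ValueError("BIC needs at least one uncensored observation")
    return -2.0 * float(max_loglik) + d_s * np.log(n_events)


@dataclass(frozen=True)
class ModelFitSummary:
    """Everything BMA needs from one fitted model."""

    model_name: str
    max_loglik: float
    d_s: int
    n_events: int

    @property
    def bic(self) -> float:
        return compute_bic(self.max_loglik, self.d_s, self.n_events)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "max_loglik": self.max_loglik,
            "d_s": self.d_s,
            "n_events": self.n_events,
            "bic": self.bic,
        }


def max_loglik_estimate(
    chain: PosteriorChain,
    loglik_fn,
    to_unconstrained=None,
    from_unconstrained=None,
    maxiter: int = 4000,
) -> float:
    """Estimate the maximized log-likelihood for the BIC.

    Deterministic numerical maximization (Nelder-Mead) started from the
    best stored draw, in an unconstrained reparameterisation supplied by
    the model; never returns less than the best stored per-draw value (on
    optimizer failure the best-draw fallback is used and logged).
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    best_idx = int(np.argmax(chain.log_likelihood))
    best_ll = float(chain.log_likelihood[best_idx])
    to_u = to_unconstrained or (lambda v: np.asarray(v, dtype=float))
    from_u = from_unconstrained or (lambda u: np.asarray(u, dtype=float))

    def neg(u):
        ll = loglik_fn(from_u(u))
        return -ll if np.isfinite(ll) else np.inf

    try:
        res = optimize.minimize(
            neg,
            to_u(chain.draws[best_idx]),
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-10},
        )
        opt_ll = -float(res.fun)
    except Exception:  # pragma: no cover - optimizer failure path
        logger.warning("optimizer failed; falling back to best stored draw")
        return best_ll
    if not np.isfinite(opt_ll) or opt_ll < best_ll:
        logger.warning("optimizer did not improve on the best stored draw")
        return best_ll
    return opt_ll


def fit_summary(model_fit) -> ModelFitSummary:
    """Build a ModelFitSummary from a fitted model object (any of the three
    model modules' fit results)."""
    ml = max_loglik_estimate(
        model_fit.chain,
        model_fit.loglik_vector,
        getattr(model_fit, "to_unconstrained", None),
        getattr(model_fit, "from_unconstrained", None),
    )
    return ModelFitSummary(model_fit.name, ml, model_fit.d_s, model_fit.n_events)


def bma_weights(bics, priors=None) -> np.ndarray:
    """Posterior model probabilities from BICs: w_s ∝ exp(-BIC_s/2) p(S=s).

    Invariant to adding a constant to every BIC; smaller BIC gives larger
    weight.  ``priors`` defaults to uniform 1/S.
    """
    bics = np.asarray(bics, dtype=float)
    if bics.size == 0:
        raise ValueError("need at least one BIC")
    if not np.all(np.isfinite(bics)):
        raise ValueError("BICs must be finite")
    if priors is None:
        priors = np.full(bics.size, 1.0 / bics.size)
    priors = np.asarray(priors, dtype=float)
    if priors.shape != bics.shape or np.any(priors < 0):
        raise ValueError("priors must be a nonnegative vector matching bics")
    priors = priors / priors.sum()
    raw = np.exp(-0.5 * (bics - bics.min())) * priors
    return raw / raw.sum()


@dataclass
class BMAResult:
    """Per-model weights (simplex) with their prior probabilities and the
    fit summaries they came from."""

    model_names: list[str]
    weights: np.ndarray
    prior_probs: np.ndarray
    summaries: list[ModelFitSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.prior_probs = np.asarray(self.prior_probs, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-8 or np.any(self.weights < 0):
            raise ValueError("weights must be a probability simplex")

    def weight(self, name: str) -> float:
        return float(self.weights[self.model_names.index(name)])

    def to_dict(self) -> dict:
        return {
            "models": [
                {
                    "model": name,
                    "weight": float(w),
                    "prior": float(p),
                    **(s.to_dict() if s else {}),
                }
                for name, w, p, s in zip(
                    self.model_names,
                    self.weights,
                    self.prior_probs,
                    self.summaries or [None] * len(self.model_names),
                )
            ]
        }


def bma_from_summaries(summaries, priors=None) -> BMAResult:
    bics = [s.bic for s in summaries]
    if priors is None:
        priors = np.full(len(bics), 1.0 / len(bics))
    w = bma_weights(bics, priors)
    return BMAResult([s.model_name for s in summaries], w, np.asarray(priors), list(summaries))


def bayes_factor(result: BMAResult, s1: str, s2: str) -> float:
    """Ratio of posterior model probabilities, adjusted for unequal prior
    model probabilities (so it reduces to the marginal-likelihood ratio)."""
    i1, i2 = result.model_names.index(s1), result.model_names.index(s2)
    w1, w2 = result.weights[i1], result.weights[i2]
    p1, p2 = result.prior_probs[i1], result.prior_probs[i2]
    if w2 == 0:
        raise ZeroDivisionError(f"model {s2!r} has zero weight")
    return float((w1 / w2) * (p2 / p1))


def bma_predictive(samplers: dict, weights, x, n_draws: int, rng) -> np.ndarray:
    """Mixture predictive: pick model s with probability w_s, then draw one
    time from that model's posterior predictive at covariates ``x``.

    ``samplers`` maps model name -> callable (x, n, rng) -> times.
    """
    names = list(samplers)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(names),):
        raise ValueError("one weight per sampler required")
    if n_draws == 0:
        return np.empty(0)
    for name, w in zip(names, weights):
        if w > 0 and samplers[name] is None:
            raise ValueError(f"missing sampler for positive-weight model {name!r}")
    counts = rng.multinomial(n_draws, weights / weights.sum())
    parts = [
        samplers[name](x, int(c), rng) for name, c in zip(names, counts) if c > 0
    ]
    out = np.concatenate(parts) if parts else np.empty(0)
    return rng.permutation(out)


def predictive_intervals(
    sampler, X, n_draws: int, rng, level: float = 0.95
) -> np.ndarray:
    """Per-subject central predictive intervals: row i is the
    (2.5%, 97.5%) empirical quantiles of the predictive draws at x_i."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    a = (1.0 - level) / 2.0
    out = np.empty((X.shape[0], 2))
    for i, x in enumerate(X):
        d = sampler(x, n_draws, rng)
        out[i] = np.quantile(d, [a, 1.0 - a])
    return out


def coverage(intervals, data) -> float:
    """Percentage of observed times falling inside their own predictive
    interval (endpoints inclusive)."""
    intervals = np.atleast_2d(np.asarray(intervals, dtype=float))
    times = np.asarray(data.times if hasattr(data, "times") else data, dtype=float)
    if intervals.shape[0] != times.shape[0]:
        raise ValueError("one interval per subject required")
    inside = (times >= intervals[:, 0]) & (times <= intervals[:, 1])
    return float(100.0 * inside.mean())
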