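"""K-component Weibull mixture with per-component covariate effects.

The density is ``sum_m w_m f(t | alpha_m, lam_im)`` with per-subject,
per-component log-scale ``lam_im = x_i . beta_m``; right-censored subjects
contribute through the mixture survivor function.  Sampling alternates a
Gibbs step on latent allocations and mixture weights (Dirichlet prior,
symmetric hyperparameter ``phi``) with slice/Metropolis updates of each
component's shape and coefficients.  Component labels are not identified
during sampling; :func:`reorder_chain` applies a post-hoc MAP-pivot
relabeling.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from survbma.core import SurvivalDataset, event_count
from survbma.mcmc import PosteriorChain, ChainConfig, map_draw, slice_step, summarize

__all__ = [
    "MixtureParams",
    "MixturePriorSpec",
    "AllocationState",
    "mixture_logdensity",
    "observed_loglik",
    "allocation_step",
    "weight_update",
    "reorder_chain",
    "fit",
    "MixtureModelFit",
]


@dataclass(frozen=True)
class MixtureParams:
    """weights (K-simplex), shapes (K,), coefficients (K, p+1)."""

    weights: np.ndarray
    alphas: np.ndarray
    betas: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "alphas", np.asarray(self.alphas, dtype=float))
        object.__setattr__(
            self, "betas", np.atleast_2d(np.asarray(self.betas, dtype=float))
        )
        if self.weights.ndim != 1 or np.any(self.weights < 0):
            raise ValueError("weights must be a nonnegative vector")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to one")
        K = len(self.weights)
        if self.alphas.shape != (K,) or np.any(self.alphas <= 0):
            raise ValueError("need K positive shapes")
        if self.betas.shape[0] != K:
            raise ValueError("need one coefficient vector per component")

    @property
    def K(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class MixturePriorSpec:
    phi: float = 1.0
    u_alpha: float = 0.01
    v_alpha: float = 0.01
    sigma_beta2: float = 100.0
    # Gamma prior on the scale in the no-covariate variant
    u_gamma: float = 0.01
    v_gamma: float = 0.01

    def __post_init__(self) -> None:
        if min(
            self.phi,
            self.u_alpha,
            self.v_alpha,
            self.sigma_beta2,
            self.u_gamma,
            self.v_gamma,
        ) <= 0:
            raise ValueError("all prior hyperparameters must be positive")


@dataclass
class AllocationState:
    """Latent component memberships z_i in 0..K-1."""

    z: np.ndarray

    def counts(self, K: int) -> np.ndarray:
        return np.bincount(self.z, minlength=K)


def _component_logf_logS(t, logt, X, params: MixtureParams):
    """(n, K) matrices of per-component log-density and log-survival."""
    lam = X @ params.betas.T  # (n, K)
    a = params.alphas[None, :]
    with np.errstate(over="ignore"):
        cum = np.power(t[:, None], a) * np.exp(lam)
        logf = np.log(a) + (a - 1.0) * logt[:, None] + lam - cum
        logS = -cum
    return logf, logS


def mixture_logdensity(t, x, params: MixtureParams):
    """log sum_m w_m f(t | alpha_m, x . beta_m), via log-sum-exp."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t <= 0):
        raise ValueError("time must be positive")
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[0] == 1 and len(t) > 1:
        X = np.repeat(X, len(t), axis=0)
    logf, _ = _component_logf_logS(t, np.log(t), X, params)
    with np.errstate(divide="ignore"):
        out = logsumexp(logf + np.log(params.weights)[None, :], axis=1)
    return out if out.size > 1 else float(out[0])


def observed_loglik(data: SurvivalDataset, params: MixtureParams) -> float:
    """Marginal (over allocations) log-likelihood:
    sum_i [delta_i log sum_m w_m f_m + (1 - delta_i) log sum_m w_m S_m]."""
    if len(data) == 0:
        return 0.0
    logf, logS = _component_logf_logS(
        data.times, np.log(data.times), data.X, params
    )
    with np.errstate(divide="ignore"):
        logw = np.log(params.weights)[None, :]
        per = np.where(
            data.events[:, None] == 1,
            logf + logw,
            logS + logw,
        )
    return float(np.sum(logsumexp(per, axis=1)))


def allocation_step(
    data: SurvivalDataset, params: MixtureParams, rng: np.random.Generator
) -> AllocationState:
    """Sample memberships with P(Z_i = m) ∝ w_m f_m(t_i)^delta_i S_m(t_i)^(1-delta_i)."""
    logf, logS = _component_logf_logS(data.times, np.log(data.times), data.X, params)
    with np.errstate(divide="ignore"):
        logw = np.log(params.weights)[None, :]
        logm = np.where(data.events[:, None] == 1, logf + logw, logS + logw)
    norm = logsumexp(logm, axis=1)
    if not np.all(np.isfinite(norm)):
        raise FloatingPointError("zero total membership mass for some subject")
    probs = np.exp(logm - norm[:, None])
    cum = np.cumsum(probs, axis=1)
    u = rng.uniform(size=len(data))
    z = np.sum(u[:, None] > cum, axis=1).astype(int)
    return AllocationState(np.minimum(z, params.K - 1))


def weight_update(
    z: AllocationState, K: int, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """Conjugate draw w | Z ~ Dirichlet(phi + n_1, ..., phi + n_K)."""
    if K == 1:
        return np.ones(1)
    return rng.dirichlet(phi + z.counts(K))


# ---------------------------------------------------------------------------
# Label-switching correction
# ---------------------------------------------------------------------------


def _component_columns(names: list[str], K: int):
    """Map component index m (1-based in names) -> ordered column indices,
    using the `stem.m` suffix convention; weight columns `w.m` included."""
    stems: dict[str, dict[int, int]] = {}
    for j, name in enumerate(names):
        if "." not in name:
            continue
        stem, _, suff = name.rpartition(".")
        if suff.isdigit():
            stems.setdefault(stem, {})[int(suff)] = j
    blocks = {}
    stem_order = sorted(stems)
    for m in range(1, K + 1):
        cols = []
        for stem in stem_order:
            if m not in stems[stem]:
                raise ValueError(f"column {stem}.{m} missing from chain")
            cols.append(stems[stem][m])
        blocks[m] = cols
    return blocks, stem_order


def reorder_chain(
    chain: PosteriorChain, K: int, pivot: np.ndarray | None = None
) -> PosteriorChain:
    """Undo label switching by permuting component blocks toward a pivot.

    For each stored draw the permutation minimizing the standardized squared
    distance between the permuted component blocks and the pivot's blocks is
    applied (component parameters are scaled by their pooled posterior spread
    so large-magnitude coefficients do not dominate).  The pivot defaults to
    the approximate MAP draw.  Per-draw log-posterior and log-likelihood are
    untouched: the observed-data likelihood is permutation invariant.
    """
    if K == 1:
        return chain
    blocks, _ = _component_columns(chain.parameter_names, K)
    pivot = map_draw(chain) if pivot is None else np.asarray(pivot, dtype=float)

    cols = np.array([blocks[m] for m in range(1, K + 1)])  # (K, q)
    B = chain.draws[:, cols]  # (n_draws, K, q)
    P = pivot[cols]  # (K, q)
    scale = np.maximum(B.reshape(-1, cols.shape[1]).std(axis=0), 1e-12)
    Bs = B / scale
    Ps = P / scale

    perms = list(itertools.permutations(range(K)))
    # score[d, p]: distance of draw d's blocks, permuted by p, from the pivot
    scores = np.stack(
        [np.sum((Bs[:, perm, :] - Ps[None, :, :]) ** 2, axis=(1, 2)) for perm in perms]
    )
    best = np.argmin(scores, axis=0)

    new_draws = chain.draws.copy()
    for pi, perm in enumerate(perms):
        rows = np.where(best == pi)[0]
        if len(rows) == 0 or perm == tuple(range(K)):
            continue
        for m_new in range(K):
            new_draws[np.ix_(rows, cols[m_new])] = chain.draws[
                np.ix_(rows, cols[perm[m_new]])
            ]
    out = PosteriorChain(
        new_draws,
        list(chain.parameter_names),
        chain.log_posterior.copy(),
        chain.log_likelihood.copy(),
    )
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _chain_names(K: int, p1: int) -> list[str]:
    names = []
    for m in range(1, K + 1):
        names.append(f"alpha.{m}")
        names.extend(f"beta{j}.{m}" for j in range(p1))
    names.extend(f"w.{m}" for m in range(1, K + 1))
    return names


def _unpack(v: np.ndarray, K: int, p1: int) -> MixtureParams:
    blk = 1 + p1
    alphas = np.array([v[m * blk] for m in range(K)])
    betas = np.stack([v[m * blk + 1 : (m + 1) * blk] for m in range(K)])
    w = np.asarray(v[K * blk :], dtype=float)
    w = w / w.sum()
    return MixtureParams(w, alphas, betas)


class MixtureModelFit:
    name = "mixture"

    def __init__(self, chain, reordered, data, K, priors, config):
        self.chain = chain
        self.reordered = reordered
        self.data = data
        self.K = K
        self.priors = priors
        self.config = config
        p1 = data.n_covariates
        self.d_s = K + K * p1 + (K - 1)
        self.n_events = event_count(data)

    def loglik_vector(self, v: np.ndarray) -> float:
        try:
            params = _unpack(v, self.K, self.data.n_covariates)
        except ValueError:
            return -np.inf
        return observed_loglik(self.data, params)

    def to_unconstrained(self, v: np.ndarray) -> np.ndarray:
        K, p1 = self.K, self.data.n_covariates
        blk = 1 + p1
        u = np.array(v[: K * blk], dtype=float)
        for m in range(K):
            u[m * blk] = np.log(u[m * blk])
        w = np.asarray(v[K * blk :], dtype=float)
        logits = np.log(w[:-1]) - np.log(w[-1])
        return np.concatenate([u, logits])

    def from_unconstrained(self, u: np.ndarray) -> np.ndarray:
        K, p1 = self.K, self.data.n_covariates
        blk = 1 + p1
        v = np.array(u[: K * blk], dtype=float)
        for m in range(K):
            v[m * blk] = np.exp(v[m * blk])
        logits = np.concatenate([u[K * blk :], [0.0]])
        w = np.exp(logits - logsumexp(logits))
        return np.concatenate([v, w])

    def predictive_draws(self, x, n_draws, rng) -> np.ndarray:
        return predictive_draws(self.chain, self.K, x, n_draws, rng)

    def summary(self):
        return summarize(self.reordered)


def _logprior(params: MixtureParams, spec: MixturePriorSpec) -> float:
    lp = float(
        gammaln(params.K * spec.phi)
        - params.K * gammaln(spec.phi)
        + (spec.phi - 1.0) * np.sum(np.log(np.maximum(params.weights, 1e-300)))
    )
    lp += float(
        np.sum(
            spec.u_alpha * np.log(spec.v_alpha)
            - gammaln(spec.u_alpha)
            + (spec.u_alpha - 1.0) * np.log(params.alphas)
            - spec.v_alpha * params.alphas
        )
    )
    lp += float(
        -0.5 * np.sum(params.betas**2) / spec.sigma_beta2
        - 0.5 * params.betas.size * np.log(2.0 * np.pi * spec.sigma_beta2)
    )
    return lp


def fit(
    data: SurvivalDataset,
    K: int = 2,
    priors: MixturePriorSpec | None = None,
    config: ChainConfig | None = None,
    empty_warn_fraction: float = 0.2,
) -> MixtureModelFit:
    """Gibbs-within-Metropolis fit of the K-component mixture.

    Each sweep: (1) sample allocations from their membership posteriors,
    (2) conjugate Dirichlet update of the weights, (3) per-component slice
    update of log(alpha_m) and Metropolis block update of beta_m against the
    complete-data conditional.  The stored per-draw log-likelihood is the
    observed-data (marginal over Z) value used in BIC, and the stored
    log-posterior is observed_loglik + log prior, whose maximizer is the
    relabeling pivot.
    """
    priors = priors or MixturePriorSpec()
    config = config or ChainConfig()
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(data) < K:
        raise ValueError("need at least K subjects")
    d = event_count(data)
    if d == 0:
        raise ValueError("dataset has no events")

    rng = np.random.default_rng(config.seed)
    n, p1 = len(data), data.n_covariates
    t, delta, X = data.times, data.events, data.X
    logt = np.log(t)

    # init: split subjects by time quantile so components start distinct
    qs = np.quantile(t, np.linspace(0, 1, K + 1))
    z = np.clip(np.searchsorted(qs[1:-1], t), 0, K - 1)
    alphas = np.ones(K)
    betas = np.zeros((K, p1))
    betas[:, 0] = np.log(max(d, 1) / np.sum(t))
    w = np.full(K, 1.0 / K)

    beta_scales = np.full((K, p1), 0.1)
    slice_w = 0.5
    n_keep = (config.n_iter - config.burn_in + config.thin - 1) // config.thin
    draws = np.empty((n_keep, K * (1 + p1) + K))
    lps = np.empty(n_keep)
    lls = np.empty(n_keep)
    kept = 0
    empty_iters = 0
    adapt_counts = np.zeros(K)

    event_mask = delta[:, None] == 1

    def _comp_matrices(w, alphas, betas):
        lam = X @ betas.T
        with np.errstate(over="ignore", divide="ignore"):
            cum = np.power(t[:, None], alphas[None, :]) * np.exp(lam)
            logf = np.log(alphas)[None, :] + (alphas - 1.0)[None, :] * logt[:, None] + lam - cum
            logm = np.where(event_mask, logf, -cum) + np.log(w)[None, :]
        return logm

    for it in range(config.n_iter):
        # allocation step, inlined for speed (see allocation_step)
        logm = _comp_matrices(w, alphas, betas)
        mx = logm.max(axis=1, keepdims=True)
        probs = np.exp(logm - mx)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.uniform(size=n)
        z = np.minimum(
            np.sum(u[:, None] > np.cumsum(probs, axis=1), axis=1), K - 1
        ).astype(int)
        counts = np.bincount(z, minlength=K)
        if np.any(counts == 0):
            empty_iters += 1
        w = rng.dirichlet(priors.phi + counts)

        for m in range(K):
            mask = z == m
            logt_m = logt[mask]
            d_m = delta[mask].astype(float)
            X_m = X[mask]
            lam_m = X_m @ betas[m]
            sd = float(d_m.sum())
            sdl = float(d_m @ logt_m)
            sdlam = float(d_m @ lam_m)

            # slice update of log(alpha_m) against the complete-data
            # conditional; only sum exp(a*log t + lam) depends on a
            def log_cond_alpha(la):
                # hard bounds keep an empty component's near-improper
                # Gamma(0.01, 0.01) conditional from drifting to 0 or inf
                if not -15.0 < la < 15.0:
                    return -np.inf
                a = np.exp(la)
                with np.errstate(over="ignore"):
                    ll = (
                        sd * la
                        + (a - 1.0) * sdl
                        + sdlam
                        - float(np.sum(np.exp(a * logt_m + lam_m)))
                    )
                if not np.isfinite(ll):
                    return -np.inf
                # Gamma prior on a plus the log-transform Jacobian
                return ll + priors.u_alpha * la - priors.v_alpha * a

            alphas[m] = np.exp(
                slice_step(log_cond_alpha, np.log(alphas[m]), slice_w, rng)
            )

            # Metropolis block update of beta_m (constant terms dropped)
            atl = alphas[m] * logt_m

            def beta_logpost(b):
                lam = X_m @ b
                with np.errstate(over="ignore"):
                    ll = float(d_m @ lam) - float(np.sum(np.exp(atl + lam)))
                if not np.isfinite(ll):
                    return -np.inf
                return ll - 0.5 * float(np.sum(b**2)) / priors.sigma_beta2

            cur_lp = beta_logpost(betas[m])
            prop = betas[m] + rng.normal(size=p1) * beta_scales[m]
            prop_lp = beta_logpost(prop)
            accepted = np.log(rng.uniform()) < prop_lp - cur_lp
            if accepted:
                betas[m] = prop
            if config.adapt and it < config.burn_in:
                adapt_counts[m] += 1
                beta_scales[m] *= np.exp(
                    adapt_counts[m] ** -0.6
                    * (float(accepted) - config.target_acceptance)
                )

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            logm = _comp_matrices(w, alphas, betas)
            mx = logm.max(axis=1)
            ll = float(np.sum(mx + np.log(np.sum(np.exp(logm - mx[:, None]), axis=1))))
            vec = []
            for m in range(K):
                vec.append(alphas[m])
                vec.extend(betas[m])
            vec.extend(w)
            draws[kept] = vec
            lls[kept] = ll
            lps[kept] = ll + _logprior(MixtureParams(w, alphas, betas), priors)
            kept += 1

    if empty_iters > empty_warn_fraction * config.n_iter:
        warnings.warn(
            f"a mixture component was empty in {empty_iters}/{config.n_iter} "
            "iterations; consider smaller K",
            RuntimeWarning,
        )

    names = _chain_names(K, p1)
    chain = PosteriorChain(draws[:kept], names, lps[:kept], lls[:kept])
    reordered = reorder_chain(chain, K)
    return MixtureModelFit(chain, reordered, data, K, priors, config)


def predictive_draws(
    chain: PosteriorChain, K: int, x, n_draws: int, rng
) -> np.ndarray:
    """Posterior predictive times at covariates ``x``: draw a stored state,
    pick a component by its weight, invert that component's Weibull CDF."""
    if len(chain) == 0:
        raise ValueError("empty chain")
    if n_draws == 0:
        return np.empty(0)
    x = np.asarray(x, dtype=float)
    p1 = x.size
    blk = 1 + p1
    idx = rng.integers(len(chain), size=n_draws)
    W = chain.draws[idx, K * blk : K * blk + K]
    W = W / W.sum(axis=1, keepdims=True)
    u_comp = rng.uniform(size=n_draws)
    comp = np.sum(u_comp[:, None] > np.cumsum(W, axis=1), axis=1)
    comp = np.minimum(comp, K - 1)
    alpha = chain.draws[idx, comp * blk]
    lam = np.einsum(
        "ij,j->i",
        chain.draws[idx[:, None], (comp * blk + 1)[:, None] + np.arange(p1)[None, :]],
        x,
    )
    u = rng.uniform(size=n_draws)
    return np.power(-np.log(u) * np.exp(-lam), 1.0 / alpha)
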