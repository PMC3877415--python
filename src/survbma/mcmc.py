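"""Generic MCMC machinery: random-walk Metropolis-Hastings, univariate
slice sampling, a block-update chain driver with burn-in adaptation, and
chain summaries.

Model modules hand ``run_chain`` a log-posterior and a log-likelihood over
an unconstrained parameter vector (positivity constraints are handled by
the caller, e.g. sampling shapes on the log scale) plus a
:class:`ChainConfig` describing per-parameter proposal scales and sampler
kinds.  Proposal scales adapt toward a target acceptance rate during
burn-in only, so the post-burn-in kernel is a valid fixed kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChainConfig",
    "PosteriorChain",
    "metropolis_step",
    "slice_step",
    "run_chain",
    "summarize",
    "map_draw",
]

METROPOLIS = "metropolis"
SLICE = "slice"


@dataclass
class ChainConfig:
    """Settings for one MCMC run.

    ``proposal_scales`` doubles as the initial slice width for slice-updated
    coordinates.  ``sampler_kinds`` is one of {"metropolis", "slice"} per
    parameter; contiguous runs of metropolis parameters are updated jointly
    as one random-walk block.
    """

    n_iter: int = 20_000
    burn_in: int = 5_000
    seed: int = 0
    proposal_scales: np.ndarray | None = None
    sampler_kinds: Sequence[str] | None = None
    adapt: bool = True
    target_acceptance: float = 0.3
    thin: int = 1

    def __post_init__(self) -> None:
        if self.n_iter <= 0:
            raise ValueError("n_iter must be positive")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.proposal_scales is not None:
            self.proposal_scales = np.asarray(self.proposal_scales, dtype=float)
            if np.any(self.proposal_scales <= 0):
                raise ValueError("proposal scales must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorChain:
    """Post-burn-in MCMC draws plus per-draw log-posterior/log-likelihood."""

    draws: np.ndarray
    parameter_names: list[str]
    log_posterior: np.ndarray
    log_likelihood: np.ndarray

    def __post_init__(self) -> None:
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=float))
        if self.draws.shape[1] != len(self.parameter_names):
            raise ValueError("column count must equal parameter name count")
        if len(self.log_posterior) != len(self.draws):
            raise ValueError("log_posterior length mismatch")
        if not np.all(np.isfinite(self.log_posterior)):
            raise ValueError("stored log_posterior values must be finite")

    def __len__(self) -> int:
        return len(self.draws)

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.parameter_names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=self.parameter_names)
        df["log_posterior"] = self.log_posterior
        df["log_likelihood"] = self.log_likelihood
        return df

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PosteriorChain":
        names = [c for c in df.columns if c not in ("log_posterior", "log_likelihood")]
        return cls(
            df[names].to_numpy(float),
            names,
            df["log_posterior"].to_numpy(float),
            df["log_likelihood"].to_numpy(float),
        )


def metropolis_step(
    log_target: Callable[[np.ndarray], float],
    current: np.ndarray,
    scale,
    rng: np.random.Generator,
    current_logp: float | None = None,
):
    """One symmetric Gaussian random-walk update of the full vector.

    Returns ``(state, accepted, log_target(state))``.  A rejected proposal
    returns the current state unchanged.
    """
    current = np.asarray(current, dtype=float)
    if current_logp is None:
        current_logp = log_target(current)
    if not np.isfinite(current_logp):
        raise ValueError("log_target must be finite at the current state")
    proposal = current + rng.normal(size=current.shape) * scale
    logp_prop = log_target(proposal)
    if np.log(rng.uniform()) < logp_prop - current_logp:
        return proposal, True, logp_prop
    return current, False, current_logp


def slice_step(
    log_target_1d: Callable[[float], float],
    current: float,
    width: float,
    rng: np.random.Generator,
    max_steps: int = 100,
) -> float:
    """Univariate slice sampler (stepping-out + shrinkage, Neal 2003)."""
    logp0 = log_target_1d(current)
    if not np.isfinite(logp0):
        raise ValueError("log_target must be finite at the current point")
    log_level = logp0 + np.log(rng.uniform())

    left = current - width * rng.uniform()
    right = left + width
    j = int(np.floor(max_steps * rng.uniform()))
    k = max_steps - 1 - j
    while j > 0 and log_target_1d(left) > log_level:
        left -= width
        j -= 1
    while k > 0 and log_target_1d(right) > log_level:
        right += width
        k -= 1

    while True:
        x = left + (right - left) * rng.uniform()
        if log_target_1d(x) > log_level:
            return x
        if x < current:
            left = x
        else:
            right = x


def _blocks(kinds: Sequence[str]) -> list[tuple[str, list[int]]]:
    """Group contiguous metropolis coordinates; slice coords stay alone."""
    blocks: list[tuple[str, list[int]]] = []
    for j, kind in enumerate(kinds):
        if kind not in (METROPOLIS, SLICE):
            raise ValueError(f"unknown sampler kind {kind!r}")
        if kind == METROPOLIS and blocks and blocks[-1][0] == METROPOLIS:
            blocks[-1][1].append(j)
        else:
            blocks.append((kind, [j]))
    return blocks


def run_chain(
    log_posterior: Callable[[np.ndarray], float],
    log_likelihood: Callable[[np.ndarray], float],
    init: np.ndarray,
    config: ChainConfig,
    parameter_names: Sequence[str] | None = None,
) -> PosteriorChain:
    """Run a block-update MCMC chain and return the post-burn-in draws.

    Deterministic: the same (init, config) pair yields a bit-identical
    chain.  Raises if the initial state has non-finite log-posterior.
    """
    state = np.array(init, dtype=float)
    p = state.size
    if parameter_names is None:
        parameter_names = [f"p{j}" for j in range(p)]
    kinds = list(config.sampler_kinds) if config.sampler_kinds else [METROPOLIS] * p
    if len(kinds) != p:
        raise ValueError("sampler_kinds length must match parameter count")
    scales = (
        np.ones(p) if config.proposal_scales is None else config.proposal_scales.copy()
    )
    if scales.size != p:
        raise ValueError("proposal_scales length must match parameter count")
    blocks = _blocks(kinds)

    rng = np.random.default_rng(config.seed)
    logp = log_posterior(state)
    if not np.isfinite(logp):
        raise ValueError("initial state has non-finite log posterior")

    n_keep = (config.n_iter - config.burn_in + config.thin - 1) // config.thin
    draws = np.empty((n_keep, p))
    lps = np.empty(n_keep)
    lls = np.empty(n_keep)
    acc_count = np.zeros(len(blocks))
    adapt_count = np.zeros(len(blocks))
    kept = 0

    for it in range(config.n_iter):
        for b, (kind, idx) in enumerate(blocks):
            if kind == METROPOLIS:

                def block_target(vals, idx=idx):
                    trial = state.copy()
                    trial[idx] = vals
                    return log_posterior(trial)

                new_vals, accepted, new_logp = metropolis_step(
                    block_target, state[idx], scales[idx], rng, current_logp=logp
                )
                state[idx] = new_vals
                logp = new_logp
                if config.adapt and it < config.burn_in:
                    adapt_count[b] += 1
                    # Robbins-Monro on the log proposal scale
                    step = adapt_count[b] ** -0.6
                    scales[idx] *= np.exp(
                        step * (float(accepted) - config.target_acceptance)
                    )
                acc_count[b] += accepted
            else:
                j = idx[0]

                def coord_target(v, j=j):
                    trial = state.copy()
                    trial[j] = v
                    return log_posterior(trial)

                state[j] = slice_step(coord_target, state[j], scales[j], rng)
                logp = log_posterior(state)
                acc_count[b] += 1

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            draws[kept] = state
            lps[kept] = logp
            lls[kept] = log_likelihood(state)
            kept += 1

    chain = PosteriorChain(draws[:kept], list(parameter_names), lps[:kept], lls[:kept])
    chain.acceptance_rates = acc_count / config.n_iter
    chain.final_scales = scales
    return chain


def summarize(chain: PosteriorChain) -> pd.DataFrame:
    """Posterior mean and central 95% credible interval per parameter.

    Interval endpoints are empirical 2.5%/97.5% quantiles with linear
    interpolation (numpy's default rule).
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    lo, hi = np.quantile(chain.draws, [0.025, 0.975], axis=0)
    return pd.DataFrame(
        {
            "mean": chain.draws.mean(axis=0),
            "q2.5": lo,
            "q97.5": hi,
            "sd": chain.draws.std(axis=0, ddof=1) if len(chain) > 1 else 0.0,
        },
        index=chain.parameter_names,
    )


def map_draw(chain: PosteriorChain) -> np.ndarray:
    """The stored draw maximizing the log-posterior (earliest on ties);
    used as the relabeling pivot for mixture chains."""
    if len(chain) == 0:
        raise ValueError("empty chain")
    return chain.draws[int(np.argmax(chain.log_posterior))].copy()
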