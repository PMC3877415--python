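"""Synthetic right-censored survival data with the structure each model
assumes, plus a case-study-shaped preset (n=219, 5 standardized covariates,
3 phenotype levels, ~37% censoring).

True latent quantities (mixture allocations, cure flags) are returned in a
side dictionary and written to a JSON sidecar, never into the dataset file,
so fitting code cannot accidentally use them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from survbma.core import SurvivalDataset

__all__ = [
    "GeneratorConfig",
    "gen_covariates",
    "gen_from_weibull",
    "gen_from_mixture",
    "gen_from_cure",
    "generate",
    "dlbcl_like_config",
    "write_dataset",
]

MODELS = ("weibull", "mixture", "cure")
CENSORING_KINDS = ("horizon", "uniform", "none")


@dataclass
class GeneratorConfig:
    model: str = "weibull"
    n: int = 219
    p: int = 5
    seed: int = 0
    censoring: str = "horizon"
    censoring_target: float = 0.37
    phenotype_levels: int = 1
    phenotype_effects: Sequence[float] | None = None
    # model-specific true parameters
    alpha: float = 1.0
    beta: Sequence[float] | None = None  # length p+1, acts on lam (weibull) / log-theta (cure)
    weights: Sequence[float] | None = None  # mixture
    alphas: Sequence[float] | None = None  # mixture
    betas: Sequence[Sequence[float]] | None = None  # mixture, (K, p+1)
    lam: float = 0.0  # cure latent-time log-scale

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.censoring_target < 1:
            raise ValueError("censoring target must lie in [0, 1)")
        if self.censoring not in CENSORING_KINDS:
            raise ValueError(f"unknown censoring kind {self.censoring!r}")
        if self.phenotype_levels < 1:
            raise ValueError("phenotype_levels must be >= 1")

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if v is not None}
        for k, v in out.items():
            if isinstance(v, np.ndarray):
                out[k] = v.tolist()
        return out


def gen_covariates(n: int, p: int, phenotype_levels: int, rng: np.random.Generator):
    """Design matrix with an intercept column of ones and p independent
    standard-normal covariates, plus uniform phenotype labels (or None)."""
    X = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(p)])
    phenotype = None
    if phenotype_levels > 1:
        labels = np.array([chr(ord("A") + l) for l in range(phenotype_levels)])
        phenotype = labels[rng.integers(phenotype_levels, size=n)]
    return X, phenotype


def _phenotype_offsets(phenotype, effects, levels):
    if phenotype is None or effects is None:
        return 0.0
    effects = np.asarray(effects, dtype=float)
    if effects.shape != (levels,):
        raise ValueError("one phenotype effect per level required")
    labels = np.array([chr(ord("A") + l) for l in range(levels)])
    idx = np.searchsorted(labels, phenotype)
    return effects[idx]


def _apply_censoring(t_latent, config: GeneratorConfig, rng, already_censored=None):
    """Return (times, events).  `horizon` censoring picks the administrative
    cutoff as the empirical (1 - target) quantile of the latent times;
    `uniform` censoring draws C_i ~ U(0, m) with m bisected so the realized
    censoring proportion matches the target."""
    n = len(t_latent)
    base_cens = (
        np.zeros(n, dtype=bool) if already_censored is None else already_censored
    )
    if config.censoring == "none" or config.censoring_target == 0:
        events = (~base_cens).astype(int)
        times = t_latent.copy()
        if np.any(~np.isfinite(times)):  # never-failing subjects
            cap = 1.01 * np.max(times[np.isfinite(times)], initial=1.0)
            times[~np.isfinite(times)] = cap
        return times, events

    if config.censoring == "horizon":
        # target is the TOTAL censoring proportion; subjects already
        # censored upstream (e.g. cured) count toward it
        target = config.censoring_target
        b = float(base_cens.mean())
        if b >= target or np.all(base_cens):
            horizon = float(np.max(t_latent[~base_cens], initial=1.0)) * 1.01
        else:
            extra = (target - b) / (1.0 - b)
            horizon = float(np.quantile(t_latent[~base_cens], 1.0 - extra))
        times = np.minimum(t_latent, horizon)
        events = ((t_latent <= horizon) & ~base_cens).astype(int)
        times[times <= 0] = np.finfo(float).tiny
        return times, events

    # uniform: bisect the upper endpoint against the drawn uniforms
    u = rng.uniform(size=n)
    tmax = float(np.max(t_latent))

    def realized(m):
        c = m * u
        return float(np.mean((c < t_latent) | base_cens))

    lo, hi = 1e-9, 100.0 * tmax
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if realized(mid) > config.censoring_target:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi) * u
    censored = (c < t_latent) | base_cens
    times = np.where(censored, np.minimum(c, t_latent), t_latent)
    times = np.maximum(times, np.finfo(float).tiny)
    return times, (~censored).astype(int)


def gen_from_weibull(config: GeneratorConfig):
    """Simulate t_i ~ Weibull(alpha, lam_i = x_i . beta) with censoring."""
    rng = np.random.default_rng(config.seed)
    X, phenotype = gen_covariates(config.n, config.p, config.phenotype_levels, rng)
    beta = (
        np.zeros(config.p + 1) if config.beta is None else np.asarray(config.beta, float)
    )
    lam = X @ beta + _phenotype_offsets(
        phenotype, config.phenotype_effects, config.phenotype_levels
    )
    u = rng.uniform(size=config.n)
    t_latent = np.power(-np.log(u) * np.exp(-lam), 1.0 / config.alpha)
    times, events = _apply_censoring(t_latent, config, rng)
    data = SurvivalDataset(
        times,
        events,
        X,
        ["intercept"] + [f"x{j}" for j in range(1, config.p + 1)],
        phenotype,
    )
    return data, {"alpha": config.alpha, "beta": beta.tolist()}


def gen_from_mixture(config: GeneratorConfig):
    """Simulate from the K-component mixture; true allocations go to the
    side dictionary only."""
    rng = np.random.default_rng(config.seed)
    w = np.asarray(config.weights if config.weights is not None else [1.0], float)
    w = w / w.sum()
    K = len(w)
    alphas = np.asarray(
        config.alphas if config.alphas is not None else np.ones(K), float
    )
    betas = (
        np.zeros((K, config.p + 1))
        if config.betas is None
        else np.atleast_2d(np.asarray(config.betas, float))
    )
    X, phenotype = gen_covariates(config.n, config.p, config.phenotype_levels, rng)
    z = rng.choice(K, size=config.n, p=w)
    lam = np.einsum("ij,ij->i", X, betas[z]) + _phenotype_offsets(
        phenotype, config.phenotype_effects, config.phenotype_levels
    )
    u = rng.uniform(size=config.n)
    t_latent = np.power(-np.log(u) * np.exp(-lam), 1.0 / alphas[z])
    times, events = _apply_censoring(t_latent, config, rng)
    data = SurvivalDataset(
        times,
        events,
        X,
        ["intercept"] + [f"x{j}" for j in range(1, config.p + 1)],
        phenotype,
    )
    truth = {
        "weights": w.tolist(),
        "alphas": alphas.tolist(),
        "betas": betas.tolist(),
        "allocations": z.tolist(),
    }
    return data, truth


def gen_from_cure(config: GeneratorConfig):
    """Simulate the promotion-time construction: N_i ~ Poisson(theta_i),
    cured subjects (N_i = 0) are administratively censored at the horizon,
    others fail at the minimum of N_i Weibull(alpha, lam) latent times."""
    rng = np.random.default_rng(config.seed)
    X, phenotype = gen_covariates(config.n, config.p, config.phenotype_levels, rng)
    beta = (
        np.zeros(config.p + 1) if config.beta is None else np.asarray(config.beta, float)
    )
    eta = X @ beta + _phenotype_offsets(
        phenotype, config.phenotype_effects, config.phenotype_levels
    )
    th = np.exp(eta)
    N = rng.poisson(th)
    cured = N == 0
    t_latent = np.empty(config.n)
    # min of N iid Weibull(alpha, lam) is Weibull(alpha, lam + log N)
    live = ~cured
    u = rng.uniform(size=int(live.sum()))
    t_latent[live] = np.power(
        -np.log(u) / (N[live] * np.exp(config.lam)), 1.0 / config.alpha
    )
    # cured subjects never fail: infinite latent time, censored at whatever
    # horizon applies to everyone (same cutoff, so censoring stays
    # noninformative about cure status)
    t_latent[cured] = np.inf
    times, events = _apply_censoring(t_latent, config, rng, already_censored=cured)
    data = SurvivalDataset(
        times,
        events,
        X,
        ["intercept"] + [f"x{j}" for j in range(1, config.p + 1)],
        phenotype,
    )
    truth = {
        "alpha": config.alpha,
        "lam": config.lam,
        "beta": beta.tolist(),
        "cured": cured.tolist(),
        "cure_fraction": float(np.mean(np.exp(-th))),
    }
    return data, truth


def generate(config: GeneratorConfig):
    if config.model == "weibull":
        return gen_from_weibull(config)
    if config.model == "mixture":
        return gen_from_mixture(config)
    return gen_from_cure(config)


def dlbcl_like_config(model: str = "weibull", seed: int = 0, **overrides) -> GeneratorConfig:
    """Preset emulating the case-study shape: n=219, 5 standardized
    covariates, 3 phenotype levels, ~37% censoring, coefficient magnitudes
    around 0.3."""
    base = dict(
        model=model,
        n=219,
        p=5,
        seed=seed,
        censoring="horizon",
        censoring_target=0.37,
        phenotype_levels=3,
        phenotype_effects=[0.0, -0.2, 0.2],
    )
    if model == "weibull":
        base.update(alpha=0.9, beta=[-1.5, -0.3, -0.3, 0.2, 0.3, -0.3])
    elif model == "mixture":
        base.update(
            weights=[0.3, 0.7],
            alphas=[4.0, 0.8],
            betas=[
                [-3.0, -0.4, 0.3, 0.0, 0.0, 0.0],
                [-1.5, -0.3, -0.3, 0.2, 0.3, -0.3],
            ],
            censoring_target=0.2,
        )
    else:
        # mean cure fraction near the mid-30s% at these coefficients
        base.update(alpha=1.0, lam=-1.0, beta=[0.1, -0.3, -0.3, 0.2, 0.3, -0.3])
    base.update(overrides)
    return GeneratorConfig(**base)


def write_dataset(data: SurvivalDataset, truth: dict, config: GeneratorConfig, path, sidecar=None):
    """Dataset CSV plus a JSON sidecar with the generator config and true
    parameters (including latent labels, kept out of the CSV)."""
    data.to_csv(path)
    sidecar = sidecar or str(path) + ".truth.json"
    with open(sidecar, "w") as fh:
        json.dump({"config": config.to_dict(), "truth": truth}, fh, indent=2)
    return sidecar
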