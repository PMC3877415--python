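"""Weibull distribution primitives, the survival dataset container, and the
Kaplan-Meier estimator.

The Weibull distribution is parameterised by a shape ``alpha > 0`` and a
log-scale ``lam = log(gamma)``:

    f(t) = alpha * t**(alpha - 1) * exp(lam) * exp(-t**alpha * exp(lam))
    S(t) = exp(-t**alpha * exp(lam))
    h(t) = alpha * t**(alpha - 1) * exp(lam)

so the log-hazard is linear in log(t).  All operations accept scalars or
numpy arrays for ``t`` and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeibullLaw",
    "SurvivalRecord",
    "SurvivalDataset",
    "weibull_logpdf",
    "weibull_logsurv",
    "weibull_hazard",
    "sample_weibull",
    "kaplan_meier",
    "event_count",
]


@dataclass(frozen=True)
class WeibullLaw:
    """Weibull law with shape ``alpha`` and log-scale ``lam = log(gamma)``."""

    alpha: float
    lam: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError(f"shape alpha must be positive, got {self.alpha}")
        if not np.isfinite(self.lam):
            raise ValueError(f"log-scale lam must be finite, got {self.lam}")

    @property
    def gamma(self) -> float:
        """Scale on the natural exponent scale, exp(lam)."""
        return float(np.exp(self.lam))


def _check_positive_time(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("time must be strictly positive")
    return t


def weibull_logpdf(t, law: WeibullLaw):
    """Log density: log(alpha) + (alpha-1)*log(t) + lam - t**alpha * exp(lam)."""
    t = _check_positive_time(t)
    out = (
        np.log(law.alpha)
        + (law.alpha - 1.0) * np.log(t)
        + law.lam
        - np.power(t, law.alpha) * np.exp(law.lam)
    )
    return out if out.ndim else float(out)


def weibull_logsurv(t, law: WeibullLaw):
    """Log survival: -t**alpha * exp(lam).  Defined for t >= 0 (0 at t=0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    out = -np.power(t, law.alpha) * np.exp(law.lam)
    return out if out.ndim else float(out)


def weibull_hazard(t, law: WeibullLaw):
    """Hazard: alpha * t**(alpha-1) * exp(lam); constant in t iff alpha == 1."""
    t = _check_positive_time(t)
    out = law.alpha * np.power(t, law.alpha - 1.0) * np.exp(law.lam)
    return out if out.ndim else float(out)


def sample_weibull(law: WeibullLaw, u):
    """Inverse-CDF sampler: t = (-log(u) / exp(lam))**(1/alpha).

    ``u`` is a uniform(0, 1) variate (scalar or array); by construction
    ``weibull_logsurv(t, law) == log(u)``.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie strictly inside (0, 1)")
    out = np.power(-np.log(u) / np.exp(law.lam), 1.0 / law.alpha)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SurvivalRecord:
    """A single subject: follow-up time, event flag, covariate vector.

    The covariate vector includes a leading intercept entry of 1 by
    convention; remaining entries are (typically standardized) scores.
    """

    time: float
    event: int
    covariates: np.ndarray

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"time must be positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


class SurvivalDataset:
    """Right-censored survival data: times, event flags, covariate matrix.

    Parameters
    ----------
    times : array of positive follow-up times (one time unit throughout).
    events : array of {0, 1}; 1 = observed failure, 0 = right-censored.
    X : design matrix (n, p+1); first column is the intercept (all ones).
    covariate_names : names for the p+1 columns of ``X``.
    phenotype : optional categorical label per subject.
    time_unit : metadata only; the math is unit-agnostic.
    """

    def __init__(
        self,
        times,
        events,
        X=None,
        covariate_names: Sequence[str] | None = None,
        phenotype=None,
        time_unit: str = "years",
    ):
        self.times = np.asarray(times, dtype=float)
        self.events = np.asarray(events, dtype=int)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.events.shape != self.times.shape:
            raise ValueError("times and events must have equal length")
        if np.any(self.times <= 0):
            raise ValueError("all times must be strictly positive")
        if not np.all(np.isin(self.events, (0, 1))):
            raise ValueError("events must be 0 (censored) or 1 (failure)")
        n = len(self.times)
        if X is None:
            X = np.ones((n, 1))
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != n:
            raise ValueError("design matrix row count must match times")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("covariates must be finite")
        if covariate_names is None:
            covariate_names = ["intercept"] + [
                f"x{j}" for j in range(1, self.X.shape[1])
            ]
        covariate_names = list(covariate_names)
        if len(covariate_names) != self.X.shape[1]:
            raise ValueError("covariate_names length must match design columns")
        if len(set(covariate_names)) != len(covariate_names):
            raise ValueError("covariate names must be unique")
        self.covariate_names = covariate_names
        if phenotype is not None:
            phenotype = np.asarray(phenotype)
            if phenotype.shape != self.times.shape:
                raise ValueError("phenotype length must match times")
        self.phenotype = phenotype
        self.time_unit = time_unit

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_covariates(self) -> int:
        """Number of design columns, p+1 (intercept included)."""
        return self.X.shape[1]

    @property
    def records(self) -> Iterator[SurvivalRecord]:
        for t, d, x in zip(self.times, self.events, self.X):
            yield SurvivalRecord(float(t), int(d), x)

    def subset(self, mask) -> "SurvivalDataset":
        mask = np.asarray(mask)
        return SurvivalDataset(
            self.times[mask],
            self.events[mask],
            self.X[mask],
            self.covariate_names,
            None if self.phenotype is None else self.phenotype[mask],
            self.time_unit,
        )

    def stratify(self) -> dict:
        """Split by phenotype level; returns {level: SurvivalDataset}."""
        if self.phenotype is None:
            raise ValueError("dataset has no phenotype labels")
        return {
            lev: self.subset(self.phenotype == lev)
            for lev in np.unique(self.phenotype)
        }

    # ------------------------------------------------------------------
    # I/O — delimited table with required columns `time`, `status`,
    # optional `phenotype`; remaining numeric columns are covariates.
    # ------------------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_unit: str = "years"):
        for col in ("time", "status"):
            if col not in df.columns:
                raise ValueError(f"required column '{col}' missing")
        cov_cols = [c for c in df.columns if c not in ("time", "status", "phenotype")]
        n = len(df)
        X = np.column_stack([np.ones(n)] + [df[c].to_numpy(float) for c in cov_cols])
        return cls(
            df["time"].to_numpy(float),
            df["status"].to_numpy(int),
            X,
            ["intercept"] + cov_cols,
            df["phenotype"].to_numpy() if "phenotype" in df.columns else None,
            time_unit,
        )

    @classmethod
    def from_csv(cls, path, sep: str = ",", **kwargs):
        return cls.from_dataframe(pd.read_csv(path, sep=sep), **kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        out = {"time": self.times, "status": self.events}
        if self.phenotype is not None:
            out["phenotype"] = self.phenotype
        for j, name in enumerate(self.covariate_names):
            if j == 0:
                continue  # intercept is implicit in the file format
            out[name] = self.X[:, j]
        return pd.DataFrame(out)

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False)


def event_count(data: SurvivalDataset) -> int:
    """Number of uncensored observations, d = sum(delta_i); this is the
    sample size entering the BIC penalty."""
    return int(np.sum(data.events))


def kaplan_meier(data: SurvivalDataset) -> pd.DataFrame:
    """Product-limit estimate of the survival function.

    Returns a frame with columns ``time``, ``n_at_risk``, ``n_events`` and
    ``survival`` containing one row per distinct event time.  The estimate
    is right-continuous and starts at 1; ties between events and censorings
    at the same time are resolved events-first (censored subjects at time t
    are still at risk for events at t).
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    order = np.argsort(data.times, kind="stable")
    times = data.times[order]
    events = data.events[order]
    n = len(times)

    rows = []
    surv = 1.0
    i = 0
    at_risk = n
    while i < n:
        t = times[i]
        j = i
        d = 0
        while j < n and times[j] == t:
            d += int(events[j])
            j += 1
        if d > 0:
            surv *= 1.0 - d / at_risk
            rows.append((t, at_risk, d, surv))
        at_risk -= j - i
        i = j
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def km_survival_at(km: pd.DataFrame, t) -> np.ndarray:
    """Evaluate a Kaplan-Meier step function at arbitrary times."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.ones_like(t)
    for i, ti in enumerate(t):
        drops = km[km["time"] <= ti]
        if len(drops):
            out[i] = drops["survival"].iloc[-1]
    return out
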