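"""Logit-linear prevalence surface in calendar time and age, fitted per sex.

The observed group prevalences p are logit-transformed and regressed on
calendar time t and a representative age a for each group:

    logit p(t, a) = beta0 + beta_t * (t - t_ref) + beta_a * a

fitted separately for women and men by ordinary (optionally
population-weighted) least squares.  The fitted surface provides, for any
(t, a),

* the predicted prevalence  p = expit(beta0 + beta_t (t - t_ref) + beta_a a)
* the cohort (directional) derivative (d/dt + d/da) p, which for the
  logit-linear surface has the closed form  p (1 - p) (beta_t + beta_a).

The cohort derivative is the left-hand side of the illness-death model's
transport equation and is what the incidence estimator consumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import statsmodels.api as sm
from scipy.special import expit as _expit
from scipy.special import logit as _logit

from .errors import DomainError, FittingError
from .tables import AgeGroup, PrevalenceTable

#: Clipping bound applied before the logit so that zero counts in young
#: groups do not produce infinities; clipped rows are reported as warnings.
LOGIT_EPS = 1e-12

#: Representative ages for the broad / open-ended groups of the German
#: long-term-care statistics layout, overridable through FitOptions.
DEFAULT_REPRESENTATIVE_AGES: Mapping[tuple[int, float], float] = {
    (0, 15.0): 7.5,
    (15, 60.0): 37.5,
    (90, math.inf): 92.5,
}


def logit(p):
    """Log-odds ln(p/(1-p)) with clipping to [LOGIT_EPS, 1-LOGIT_EPS].

    Raises :class:`DomainError` for p outside [0, 1].
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise DomainError(f"logit requires p in [0, 1], got {p!r}")
    out = _logit(np.clip(arr, LOGIT_EPS, 1 - LOGIT_EPS))
    return float(out) if out.ndim == 0 else out


def expit(x):
    """Inverse logit 1/(1 + exp(-x))."""
    out = _expit(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FitOptions:
    """Choices the grouped-data regression leaves open.

    age_assignment maps (lower, upper) -> representative age for groups whose
    midpoint is not wanted (defaults cover the broad/open groups);
    include_groups filters groups out of the fit; weights is ``"none"`` (OLS)
    or ``"population"`` (WLS with n_pop weights).
    """

    age_assignment: Mapping[tuple[int, float], float] = field(
        default_factory=lambda: dict(DEFAULT_REPRESENTATIVE_AGES)
    )
    include_groups: Callable[[AgeGroup], bool] = lambda g: True
    weights: str = "none"
    t_ref: float = 2015.0

    def __post_init__(self) -> None:
        if self.weights not in ("none", "population"):
            raise ValueError(f"weights must be 'none' or 'population', got {self.weights!r}")
        for (lo, hi), rep in self.age_assignment.items():
            if not (lo <= rep and (math.isinf(hi) or rep < hi)):
                raise ValueError(
                    f"representative age {rep} lies outside its group [{lo}, {hi})"
                )


def assign_age(group: AgeGroup, options: FitOptions | None = None) -> float:
    """Representative age for a group: configured constant, else the midpoint."""
    options = options or FitOptions()
    key = (group.lower, group.upper)
    if key in options.age_assignment:
        return float(options.age_assignment[key])
    return group.midpoint()


@dataclass(frozen=True)
class LogitPrevalenceModel:
    """Fitted logit-linear prevalence surface for one sex."""

    sex: str
    beta0: float
    beta_t: float
    beta_a: float
    t_ref: float
    fit_points: int
    residual_ss: float

    def __post_init__(self) -> None:
        if self.fit_points < 3:
            raise FittingError(
                f"logit-linear model needs >= 3 fit points, got {self.fit_points}"
            )
        for name in ("beta0", "beta_t", "beta_a"):
            if not math.isfinite(getattr(self, name)):
                raise FittingError(f"non-finite coefficient {name}")

    def linear_predictor(self, year, age):
        return (
            self.beta0
            + self.beta_t * (np.asarray(year, dtype=float) - self.t_ref)
            + self.beta_a * np.asarray(age, dtype=float)
        )

    def predict_prevalence(self, year, age):
        """Predicted prevalence, strictly inside (0, 1)."""
        return expit(self.linear_predictor(year, age))

    def cohort_derivative(self, year, age):
        """(d/dt + d/da) p along an aging cohort, closed form p(1-p)(beta_t+beta_a)."""
        p = self.predict_prevalence(year, age)
        return p * (1.0 - p) * (self.beta_t + self.beta_a)

    # -- flat key=value serialization ------------------------------------
    def to_text(self, path: str | Path) -> None:
        lines = [
            f"sex={self.sex}",
            f"beta0={self.beta0!r}",
            f"beta_t={self.beta_t!r}",
            f"beta_a={self.beta_a!r}",
            f"t_ref={self.t_ref!r}",
            f"fit_points={self.fit_points}",
            f"residual_ss={self.residual_ss!r}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "LogitPrevalenceModel":
        kv = {}
        for line in Path(path).read_text().splitlines():
            if line.strip():
                k, v = line.split("=", 1)
                kv[k.strip()] = v.strip()
        return cls(
            sex=kv["sex"],
            beta0=float(kv["beta0"]),
            beta_t=float(kv["beta_t"]),
            beta_a=float(kv["beta_a"]),
            t_ref=float(kv["t_ref"]),
            fit_points=int(kv["fit_points"]),
            residual_ss=float(kv["residual_ss"]),
        )


def predict_prevalence(model: LogitPrevalenceModel, year, age):
    return model.predict_prevalence(year, age)


def cohort_derivative(model: LogitPrevalenceModel, year, age):
    return model.cohort_derivative(year, age)


def fit_logit_linear(
    data: PrevalenceTable,
    sex: str,
    options: FitOptions | None = None,
) -> LogitPrevalenceModel:
    """Fit logit(prevalence) ~ (year - t_ref) + representative age for one sex.

    Uses ordinary least squares (or WLS with population weights when
    ``options.weights == "population"``).  Raises :class:`FittingError` for a
    rank-deficient design, e.g. a single calendar year or a single age group.
    """
    options = options or FitOptions()
    sub = data.df[data.df["sex"] == sex]
    rows = []
    for _, row in sub.iterrows():
        group = AgeGroup(int(row["age_lo"]), float(row["age_hi"]))
        if not options.include_groups(group):
            continue
        rows.append(
            (
                float(row["year"]),
                assign_age(group, options),
                float(row["prevalence"]),
                float(row["n_pop"]),
            )
        )
    if len(rows) < 3:
        raise FittingError(
            f"need >= 3 usable (year, group) points for sex={sex!r}, got {len(rows)}"
        )
    arr = np.asarray(rows, dtype=float)
    year, age, prev, n_pop = arr.T
    at_bound = (prev <= 0.0) | (prev >= 1.0)
    if at_bound.any():
        warnings.warn(
            f"{int(at_bound.sum())} prevalence value(s) exactly 0 or 1 for sex={sex!r} "
            f"were clipped to [{LOGIT_EPS}, 1-{LOGIT_EPS}] before the logit "
            f"(first: year={year[at_bound][0]:.0f}, age={age[at_bound][0]})",
            stacklevel=2,
        )
    y = logit(prev)
    X = np.column_stack([np.ones_like(year), year - options.t_ref, age])
    if np.linalg.matrix_rank(X) < 3:
        raise FittingError(
            f"rank-deficient design for sex={sex!r}: need at least two distinct "
            "years and two distinct representative ages"
        )
    if options.weights == "population":
        res = sm.WLS(y, X, weights=n_pop).fit()
    else:
        res = sm.OLS(y, X).fit()
    beta0, beta_t, beta_a = res.params
    return LogitPrevalenceModel(
        sex=sex,
        beta0=float(beta0),
        beta_t=float(beta_t),
        beta_a=float(beta_a),
        t_ref=options.t_ref,
        fit_points=len(rows),
        residual_ss=float(np.sum(res.resid**2)),
    )
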