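"""Incidence of the ill (care-needing) state from prevalence and mortality.

The illness-death model (healthy -> ill -> dead, healthy -> dead) links the
age- and time-specific prevalence p(t, a) to the incidence rate i, remission
rate r, all-cause mortality m of the total population and the mortality rate
ratio R = m_ill / m_healthy through the transport equation

    (d/dt + d/da) p = (1 - p) * [ i - m p (R - 1) / (p (R - 1) + 1) ] - r p.

Solving for i gives the estimator implemented here:

    i = (dp + r p) / (1 - p) + m p (R - 1) / (p (R - 1) + 1),

with dp the cohort derivative (d/dt + d/da) p.  Given aggregated prevalence
(through the fitted logit-linear surface) and period life-table mortality,
this turns purely cross-sectional registry data into age-specific incidence
rates without any longitudinal follow-up.  R and r are external assumptions;
scenario grids over R bracket the unknown differential mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, DomainError
from .prevalence import LogitPrevalenceModel
from .tables import FLAG_NEGATIVE, FLAG_OK, IncidenceTable, MortalityTable


def _validate_inputs(p, dp, m, R, r):
    p, dp, m, R, r = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (p, dp, m, R, r))
    )
    if np.any((p < 0) | (p >= 1)):
        raise DomainError(f"prevalence must satisfy 0 <= p < 1, got p={p}")
    if np.any(m < 0):
        raise DomainError("mortality rate m must be >= 0")
    if np.any(R <= 0):
        raise DomainError("mortality rate ratio R must be > 0")
    if np.any(r < 0):
        raise DomainError("remission rate r must be >= 0")
    denom = p * (R - 1.0) + 1.0
    if np.any(denom <= 0):
        raise DomainError(
            "p * (R - 1) + 1 <= 0: the all-cause mortality decomposition is "
            "undefined (possible only for R < 1 with large p)"
        )
    return p, dp, m, R, r, denom


def estimate_incidence(p, dp, m, R, r=0.0):
    """Incidence rate per person-year from the rearranged transport equation.

    Parameters are the prevalence p in [0, 1), its cohort derivative dp per
    year, the all-cause mortality m of the total population per person-year,
    the mortality rate ratio R > 0 and the remission rate r >= 0.  Inputs
    broadcast like numpy arrays.  Negative estimates are returned as-is,
    never clipped: they are a diagnostic, not noise.
    """
    p, dp, m, R, r, denom = _validate_inputs(p, dp, m, R, r)
    i = (dp + r * p) / (1.0 - p) + m * p * (R - 1.0) / denom
    return float(i) if i.ndim == 0 else i


def verify_pde_consistency(p, dp, m, R, r=0.0):
    """Residual of the forward transport equation at the estimated incidence.

    Substitutes i = estimate_incidence(p, dp, m, R, r) back into the
    right-hand side (1-p)[i - m p (R-1)/(p(R-1)+1)] - r p and returns the
    difference to dp.  The estimator is an exact algebraic rearrangement, so
    the residual is zero to rounding for every admissible input.
    """
    p, dp, m, R, r, denom = _validate_inputs(p, dp, m, R, r)
    i = (dp + r * p) / (1.0 - p) + m * p * (R - 1.0) / denom
    rhs = (1.0 - p) * (i - m * p * (R - 1.0) / denom) - r * p
    resid = rhs - dp
    return float(resid) if resid.ndim == 0 else resid


@dataclass(frozen=True)
class ScenarioConfig:
    """Scenario grid for the estimation run.

    R holds one mortality rate ratio per scenario (defaults bracket the
    literature range with 3.2 and 1.17); r is the remission rate assumed in
    the estimation (default 0: need of care treated as chronic and
    irreversible); year is the evaluation calendar year; ages the evaluation
    grid (default single years 50..90).
    """

    R: tuple[float, ...] = (3.2, 1.17)
    r: float = 0.0
    year: float = 2015.0
    ages: tuple[float, ...] = tuple(range(50, 91))
    sexes: tuple[str, ...] = ("female", "male")

    def __post_init__(self) -> None:
        if not self.R or any(x <= 0 for x in self.R):
            raise ValueError("ScenarioConfig.R must be non-empty with all values > 0")
        if self.r < 0:
            raise ValueError("remission rate r must be >= 0")
        if not self.ages or any(a < 0 for a in self.ages):
            raise ValueError("ages must be non-empty and non-negative")


def run_scenarios(
    models: Mapping[str, LogitPrevalenceModel],
    mortality: MortalityTable,
    config: ScenarioConfig,
) -> IncidenceTable:
    """Evaluate the incidence estimator over (sex, age, R) scenario grids.

    For every combination, the prevalence and its cohort derivative come from
    the fitted logit-linear surface at (config.year, age), the all-cause
    mortality from the (bilinearly interpolated) mortality table, and the
    incidence from :func:`estimate_incidence`, scaled to per 1000
    person-years.  Rows with a negative estimate are flagged and retained.
    Mortality coverage is checked before any estimation.
    """
    ages = np.asarray(config.ages, dtype=float)
    for sex in config.sexes:
        if sex not in models:
            raise DomainError(f"no fitted prevalence model for sex={sex!r}")
        try:
            mortality.rate(np.full_like(ages, config.year), ages, sex)
        except CoverageError as exc:
            raise CoverageError(
                f"mortality table does not cover year={config.year}, "
                f"ages {ages.min():.0f}-{ages.max():.0f} for sex={sex!r}: {exc}"
            ) from None
    rows = []
    for sex in config.sexes:
        model = models[sex]
        p = np.asarray(model.predict_prevalence(config.year, ages))
        dp = np.asarray(model.cohort_derivative(config.year, ages))
        m = np.asarray(mortality.rate(np.full_like(ages, config.year), ages, sex))
        for R in config.R:
            i = np.asarray(estimate_incidence(p, dp, m, R, config.r))
            for age, inc in zip(ages, i):
                rows.append(
                    {
                        "year": config.year,
                        "sex": sex,
                        "age": age,
                        "R": R,
                        "r": config.r,
                        "incidence_per_1000py": 1000.0 * inc,
                        "flag": FLAG_NEGATIVE if inc < 0 else FLAG_OK,
                    }
                )
    return IncidenceTable(pd.DataFrame(rows))
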