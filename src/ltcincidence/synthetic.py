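"""Synthetic illness-death data with known ground truth.

Two generators share one three-state process (healthy -> ill -> dead, with
healthy -> dead and optional ill -> healthy remission):

* a deterministic two-compartment cohort solver (fixed-step classical
  Runge-Kutta) that integrates the healthy/ill occupancies along birth
  cohorts and yields the exact prevalence surface p(t, a) and the
  prevalence-weighted all-cause mortality m(t, a);
* a stochastic microsimulation that samples individual event histories from
  piecewise-constant hazards on a fine age grid, as an independent oracle
  for the solver.

Both can be aggregated into registry-style tables (grouped biennial
prevalence, single-age period mortality) so the whole estimation pipeline is
testable by parameter recovery without any external download.

Ground-truth regimes
--------------------
:class:`GompertzTruth`
    Incidence i(a) = i0 * exp(beta_i * a) and care-free mortality
    m0(a) = alpha * exp(gamma * a), the exponential-in-age regime the
    estimated rates exhibit.  The logit-linear prevalence model is then an
    approximation, so pipeline recovery carries a documented
    misspecification error.
:class:`LogitLinearTruth`
    The prevalence surface itself is chosen logit-linear in (t, a) and the
    incidence that generates it is derived by inverting the transport
    equation; feeding it forward reproduces the surface exactly, so the
    pipeline is well-specified and recovery errors isolate numerical error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import IntegrationError, ValidationError
from .estimator import ScenarioConfig, estimate_incidence, run_scenarios
from .prevalence import FitOptions, LogitPrevalenceModel, fit_logit_linear
from .tables import (
    PFLEGESTATISTIK_GROUPS,
    AgeGroup,
    MortalityTable,
    PrevalenceTable,
)

# --------------------------------------------------------------------------
# ground truth parameterisations
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticTruth:
    """Base class: rates of the generating three-state process.

    Subclasses implement ``incidence(t, a)`` (healthy -> ill, per
    person-year), ``mortality_free(t, a)`` (healthy -> dead), and
    ``initial_prevalence(birth_year)``.  Ill mortality is R * m0 by
    construction; ``r`` is the remission rate (ill -> healthy).
    """

    R: float = 3.2
    r: float = 0.0

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValidationError("mortality rate ratio R must be > 0")
        if self.r < 0:
            raise ValidationError("remission rate r must be >= 0")

    def incidence(self, t, a):
        raise NotImplementedError

    def mortality_free(self, t, a):
        raise NotImplementedError

    def initial_prevalence(self, birth_year):
        return np.zeros_like(np.asarray(birth_year, dtype=float))


@dataclass(frozen=True)
class GompertzTruth(SyntheticTruth):
    """Exponential-in-age incidence and background mortality.

    i(a) = i0 exp(beta_i a); m0(a) = alpha exp(gamma a); both time-invariant.
    """

    i0: float = 1e-5
    beta_i: float = 0.1
    alpha: float = 5e-5
    gamma: float = 0.095

    def __post_init__(self) -> None:
        super().__post_init__()
        if min(self.i0, self.alpha) < 0:
            raise ValidationError("rates must be >= 0")

    def incidence(self, t, a):
        a = np.asarray(a, dtype=float)
        return self.i0 * np.exp(self.beta_i * a) * np.ones_like(np.asarray(t, dtype=float))

    def mortality_free(self, t, a):
        a = np.asarray(a, dtype=float)
        return self.alpha * np.exp(self.gamma * a) * np.ones_like(np.asarray(t, dtype=float))


@dataclass(frozen=True)
class LogitLinearTruth(SyntheticTruth):
    """Truth whose prevalence surface is exactly logit-linear in (t, a).

    The surface p(t, a) = expit(beta0 + beta_t (t - t_ref) + beta_a a) is
    chosen first; the incidence that generates it under care-free mortality
    m0(a) = alpha exp(gamma a), ratio R and remission r is derived by
    inverting the transport equation.  The all-cause mortality of the mixed
    population is m = m0 (1 + p (R - 1)).
    """

    beta0: float = -11.5
    beta_t: float = 0.02
    beta_a: float = 0.12
    t_ref: float = 2015.0
    alpha: float = 5e-5
    gamma: float = 0.095

    def prevalence(self, t, a):
        t = np.asarray(t, dtype=float)
        a = np.asarray(a, dtype=float)
        return expit(self.beta0 + self.beta_t * (t - self.t_ref) + self.beta_a * a)

    def cohort_derivative(self, t, a):
        p = self.prevalence(t, a)
        return p * (1.0 - p) * (self.beta_t + self.beta_a)

    def mortality_free(self, t, a):
        a = np.asarray(a, dtype=float)
        return self.alpha * np.exp(self.gamma * a) * np.ones_like(np.asarray(t, dtype=float))

    def mortality_total(self, t, a):
        p = self.prevalence(t, a)
        return self.mortality_free(t, a) * (1.0 + p * (self.R - 1.0))

    def incidence(self, t, a):
        p = self.prevalence(t, a)
        dp = self.cohort_derivative(t, a)
        m = self.mortality_total(t, a)
        return estimate_incidence(p, dp, m, self.R, self.r)

    def initial_prevalence(self, birth_year):
        return self.prevalence(np.asarray(birth_year, dtype=float), 0.0)


def default_truths() -> dict[str, GompertzTruth]:
    """Per-sex default ground truths of the synthetic study population.

    Chosen so that men have the higher incidence below the mid-60s and women
    above (crossover near age 65), with adult rates in the single-digit to
    low-hundreds per 1000 person-years range and women's background
    mortality below men's.
    """
    return {
        "female": GompertzTruth(i0=5.2e-6, beta_i=0.110, alpha=2.5e-5, gamma=0.100, R=3.2, r=0.0),
        "male": GompertzTruth(i0=1.0e-5, beta_i=0.100, alpha=5.0e-5, gamma=0.095, R=3.2, r=0.0),
    }


def default_logitlinear_truths() -> dict[str, LogitLinearTruth]:
    return {
        "female": LogitLinearTruth(beta0=-11.8, beta_t=0.02, beta_a=0.124, alpha=2.5e-5, gamma=0.100, R=3.2, r=0.0),
        "male": LogitLinearTruth(beta0=-11.2, beta_t=0.02, beta_a=0.115, alpha=5.0e-5, gamma=0.095, R=3.2, r=0.0),
    }


# --------------------------------------------------------------------------
# deterministic cohort solver
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PrevalenceSurface:
    """Exact (year, age) grid of the generating process.

    p[iy, ia] is the prevalence, m_total the all-cause mortality of the
    mixture and alive the surviving fraction of the birth cohort (the
    person-weight used when aggregating ages into groups).
    """

    years: np.ndarray
    ages: np.ndarray
    p: np.ndarray
    m_total: np.ndarray
    alive: np.ndarray

    def at(self, year, age) -> tuple[float, float]:
        iy = int(np.flatnonzero(self.years == year)[0])
        ia = int(np.flatnonzero(self.ages == age)[0])
        return float(self.p[iy, ia]), float(self.m_total[iy, ia])


def _build_mesh(a_max: float, step: float, required: Iterable[float]) -> np.ndarray:
    mesh = np.arange(0.0, a_max + 0.5 * step, step)
    mesh = np.union1d(np.round(mesh, 12), np.round(np.asarray(list(required), float), 12))
    return mesh[mesh <= a_max + 1e-9]


def _integrate_cohorts(
    truth: SyntheticTruth,
    births: np.ndarray,
    mesh: np.ndarray,
    record_ages: np.ndarray,
):
    """Classical RK4 along cohorts, vectorised over birth years.

    Returns (p, m_total, alive), each of shape (n_cohorts, n_record_ages).
    """
    births = np.asarray(births, dtype=float)
    p0 = np.asarray(truth.initial_prevalence(births), dtype=float)
    S = 1.0 - p0
    C = p0.copy()

    def rhs(a, S, C):
        t = births + a
        i = truth.incidence(t, a)
        m0 = truth.mortality_free(t, a)
        m1 = truth.R * m0
        dS = -(i + m0) * S + truth.r * C
        dC = i * S - (m1 + truth.r) * C
        return dS, dC

    rec_index = {round(float(a), 12): k for k, a in enumerate(record_ages)}
    p_out = np.full((len(births), len(record_ages)), np.nan)
    m_out = np.full_like(p_out, np.nan)
    alive_out = np.full_like(p_out, np.nan)

    def record(a, S, C):
        k = rec_index.get(round(float(a), 12))
        if k is not None:
            n = S + C
            t = births + a
            m0 = truth.mortality_free(t, a)
            p_out[:, k] = C / n
            m_out[:, k] = (m0 * S + truth.R * m0 * C) / n
            alive_out[:, k] = n

    record(mesh[0], S, C)
    for a, a_next in zip(mesh[:-1], mesh[1:]):
        h = a_next - a
        k1S, k1C = rhs(a, S, C)
        k2S, k2C = rhs(a + 0.5 * h, S + 0.5 * h * k1S, C + 0.5 * h * k1C)
        k3S, k3C = rhs(a + 0.5 * h, S + 0.5 * h * k2S, C + 0.5 * h * k2C)
        k4S, k4C = rhs(a_next, S + h * k3S, C + h * k3C)
        S = S + (h / 6.0) * (k1S + 2 * k2S + 2 * k3S + k4S)
        C = C + (h / 6.0) * (k1C + 2 * k2C + 2 * k3C + k4C)
        if not (np.all(np.isfinite(S)) and np.all(np.isfinite(C))):
            bad = int(np.flatnonzero(~(np.isfinite(S) & np.isfinite(C)))[0])
            raise IntegrationError(
                f"non-finite state at age {a_next:.3f} for cohort born {births[bad]:.0f}"
            )
        record(a_next, S, C)
    return p_out, m_out, alive_out


def solve_cohort(
    truth: SyntheticTruth,
    birth_year: float,
    eval_ages: Sequence[float],
    step: float = 0.05,
):
    """Integrate one birth cohort and report (p, m_total, alive) at eval_ages.

    The integration mesh is the uniform step grid refined to land exactly on
    every evaluation age, so fractional ages (e.g. for finite-difference
    derivatives along the cohort) are solver-exact, not interpolated.
    """
    eval_ages = np.asarray(sorted(float(a) for a in eval_ages))
    mesh = _build_mesh(float(eval_ages.max()), step, eval_ages)
    p, m, alive = _integrate_cohorts(truth, np.asarray([birth_year]), mesh, eval_ages)
    return p[0], m[0], alive[0]


def solve_prevalence_forward(
    truth: SyntheticTruth,
    years: Sequence[float],
    ages: Sequence[float],
    step: float = 0.05,
) -> PrevalenceSurface:
    """Forward-solve the compartment model on a (year, age) grid.

    Every (year, age) cell is read off the cohort born year - age, integrated
    from birth with p(birth) = truth.initial_prevalence.
    """
    if step > 0.25:
        raise ValidationError(f"integration step must be <= 0.25 years, got {step}")
    years = np.asarray(sorted(set(float(y) for y in years)))
    ages = np.asarray(sorted(set(float(a) for a in ages)))
    births = np.asarray(
        sorted({round(y - a, 9) for y in years for a in ages})
    )
    mesh = _build_mesh(float(ages.max()), step, ages)
    p_c, m_c, alive_c = _integrate_cohorts(truth, births, mesh, ages)
    birth_idx = {b: i for i, b in enumerate(births)}
    age_idx = {round(float(a), 9): k for k, a in enumerate(ages)}
    ny, na = len(years), len(ages)
    p = np.empty((ny, na))
    m = np.empty((ny, na))
    alive = np.empty((ny, na))
    for iy, y in enumerate(years):
        for ia, a in enumerate(ages):
            ic = birth_idx[round(y - a, 9)]
            p[iy, ia] = p_c[ic, age_idx[round(float(a), 9)]]
            m[iy, ia] = m_c[ic, age_idx[round(float(a), 9)]]
            alive[iy, ia] = alive_c[ic, age_idx[round(float(a), 9)]]
    return PrevalenceSurface(years=years, ages=ages, p=p, m_total=m, alive=alive)


# --------------------------------------------------------------------------
# stochastic microsimulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MicrosimCounts:
    """Aggregated microsimulation output at single ages per calendar year.

    df columns: year, age, n_alive, n_ill, deaths, person_years (deaths and
    exposure within [age, age+1) of the same cohort).  py_ill is the total
    person-time spent in the ill state across all simulated cohorts.
    """

    df: pd.DataFrame
    n_per_cohort: int
    py_ill: float


def _simulate_cohort(
    truth: SyntheticTruth,
    birth: float,
    n: int,
    rng: np.random.Generator,
    a_max: float,
    dt: float,
):
    """Event histories for one cohort: returns (death_age, episodes).

    death_age is +inf for persons alive at a_max.  episodes is a list of
    (onset_age, end_age) array pairs, one pair per transition round (end is
    death, remission, or a_max).  Hazards are piecewise constant on the
    dt-grid, evaluated at step midpoints; event times are sampled by exact
    inversion of the resulting piecewise-linear cumulative hazard.
    """
    K = int(math.ceil(a_max / dt))
    edges = np.arange(K + 1) * dt
    mids = edges[:-1] + 0.5 * dt
    t_mid = birth + mids
    i_step = np.clip(np.asarray(truth.incidence(t_mid, mids), float), 0.0, None)
    m0_step = np.clip(np.asarray(truth.mortality_free(t_mid, mids), float), 0.0, None)
    m1_step = truth.R * m0_step
    tiny = 1e-300
    lam_h = np.maximum(i_step + m0_step, tiny)
    lam_i = np.maximum(m1_step + truth.r, tiny)
    cum_h = np.concatenate([[0.0], np.cumsum(lam_h * dt)])
    cum_i = np.concatenate([[0.0], np.cumsum(lam_i * dt)])

    def cum_at(cum_edges, rates, age):
        k = np.minimum((age / dt).astype(int), K - 1)
        return cum_edges[k] + rates[k] * (age - edges[k])

    death_age = np.full(n, np.inf)
    episodes: list[tuple[np.ndarray, np.ndarray]] = []

    # initially ill fraction (relevant for surface-consistent truths)
    p0 = float(np.asarray(truth.initial_prevalence(birth)))
    state_ill = rng.random(n) < p0
    cur_age = np.zeros(n)
    active = np.ones(n, dtype=bool)

    while active.any():
        idx_h = np.flatnonzero(active & ~state_ill)
        idx_i = np.flatnonzero(active & state_ill)
        active = np.zeros(n, dtype=bool)

        if idx_h.size:
            start = cum_at(cum_h, lam_h, cur_age[idx_h])
            target = start + rng.exponential(size=idx_h.size)
            k = np.searchsorted(cum_h, target, side="right") - 1
            beyond = k >= K
            ks = np.minimum(k, K - 1)
            age_ev = edges[ks] + (target - cum_h[ks]) / lam_h[ks]
            age_ev = np.where(beyond, np.inf, np.minimum(age_ev, a_max))
            to_ill = (~beyond) & (rng.random(idx_h.size) < i_step[ks] / lam_h[ks])
            died = (~beyond) & ~to_ill
            death_age[idx_h[died]] = age_ev[died]
            sel = idx_h[to_ill]
            cur_age[sel] = age_ev[to_ill]
            state_ill[sel] = True
            active[sel] = True

        if idx_i.size:
            onset = cur_age[idx_i].copy()
            start = cum_at(cum_i, lam_i, onset)
            target = start + rng.exponential(size=idx_i.size)
            k = np.searchsorted(cum_i, target, side="right") - 1
            beyond = k >= K
            ks = np.minimum(k, K - 1)
            age_ev = edges[ks] + (target - cum_i[ks]) / lam_i[ks]
            age_ev = np.where(beyond, a_max, np.minimum(age_ev, a_max))
            remit = (~beyond) & (rng.random(idx_i.size) < truth.r / lam_i[ks])
            died = (~beyond) & ~remit
            death_age[idx_i[died]] = age_ev[died]
            episodes.append((idx_i, onset, np.where(beyond, a_max, age_ev)))
            sel = idx_i[remit]
            cur_age[sel] = age_ev[remit]
            state_ill[sel] = False
            active[sel] = True

    return death_age, episodes


def microsimulate(
    truth: SyntheticTruth,
    n: int,
    seed: int,
    years: Sequence[int] = (2015,),
    ages: Sequence[int] = tuple(range(0, 100)),
    dt: float = 0.05,
) -> MicrosimCounts:
    """Per-person competing-risk simulation aggregated to single-age counts.

    One birth cohort of ``n`` persons is simulated for every (year, age)
    combination requested (cohort born year - age, followed from birth).
    Counts are evaluated at the exact attained age; deaths and person-years
    cover [age, age+1) within the same cohort.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    years = sorted(set(int(y) for y in years))
    ages = sorted(set(int(a) for a in ages))
    rows = []
    py_ill_total = 0.0
    needed: dict[float, list[tuple[int, int]]] = {}
    for y in years:
        for a in ages:
            needed.setdefault(float(y - a), []).append((y, a))
    for birth in sorted(needed):
        max_a = max(a for (_y, a) in needed[birth]) + 1.0
        if n == 0:
            for y, a in needed[birth]:
                rows.append((y, a, 0, 0, 0, 0.0))
            continue
        death_age, episodes = _simulate_cohort(truth, birth, n, rng, max_a, dt)
        for idx, onset, end in episodes:
            py_ill_total += float(np.sum(end - onset))
        for y, a in needed[birth]:
            alive = death_age > a
            ill = np.zeros(n, dtype=bool)
            for idx, onset, end in episodes:
                ill[idx[(onset <= a) & (a < end)]] = True
            deaths = np.sum((death_age >= a) & (death_age < a + 1))
            py = float(np.sum(np.clip(np.minimum(death_age, a + 1.0) - a, 0.0, 1.0)[death_age > a]))
            rows.append((y, a, int(alive.sum()), int((ill & alive).sum()), int(deaths), py))
    df = pd.DataFrame(rows, columns=["year", "age", "n_alive", "n_ill", "deaths", "person_years"])
    return MicrosimCounts(df=df.sort_values(["year", "age"]).reset_index(drop=True), n_per_cohort=n, py_ill=py_ill_total)


# --------------------------------------------------------------------------
# table emission
# --------------------------------------------------------------------------


def emit_tables(
    source: PrevalenceSurface | MicrosimCounts,
    sex: str,
    years: Sequence[int] | None = None,
    groups: Sequence[AgeGroup] = PFLEGESTATISTIK_GROUPS,
    cohort_size: int = 1_000_000,
) -> tuple[PrevalenceTable, MortalityTable]:
    """Aggregate a surface or microsimulation into registry-style tables.

    Group prevalence is the person-weighted mean of p over the surface ages
    in the group (weights: surviving cohort fraction for the deterministic
    surface, observed alive counts for the microsimulation); the mortality
    table carries the all-cause rates at the integral surface ages.  When the
    surface contains half-integer ages these are interpreted as the midpoints
    of single-year age classes and preferred for the prevalence aggregation,
    so a group like [60, 65) averages the classes centred at 60.5 ... 64.5 --
    consistent with its representative (midpoint) age.  Output is validated
    by the table containers.
    """
    if isinstance(source, PrevalenceSurface):
        years = [int(y) for y in (years if years is not None else source.years)]
        ages = source.ages
        is_int = np.isclose(ages, np.round(ages))
        prev_ages = ages[~is_int] if (~is_int).any() else ages
        mort_ages = ages[is_int]
        if mort_ages.size == 0:
            raise ValidationError("surface has no integral ages to emit mortality at")
        prev_age_set = set(prev_ages)
        prev_rows = []
        mort_rows = []
        for y in years:
            iy = int(np.flatnonzero(source.years == y)[0])
            for g in groups:
                sel = np.array([a in prev_age_set and g.contains(a) for a in ages])
                if not sel.any():
                    raise ValidationError(
                        f"grouping {g.label} covers no age of the surface"
                    )
                w = source.alive[iy, sel] * cohort_size
                n_pop = int(round(w.sum()))
                n_care = int(round(float(np.sum(w * source.p[iy, sel]))))
                prev_rows.append((y, sex, g.lower, g.upper, n_care, n_pop))
            for ia, a in enumerate(ages):
                if is_int[ia]:
                    mort_rows.append((y, sex, int(round(a)), float(source.m_total[iy, ia])))
        covered = {a for g in groups for a in prev_ages if g.contains(a)}
        if covered != set(prev_ages):
            raise ValidationError("grouping does not cover all surface ages")
    else:
        df = source.df
        years = [int(y) for y in (years if years is not None else sorted(df["year"].unique()))]
        ages = np.sort(df["age"].unique())
        prev_rows = []
        mort_rows = []
        for y in years:
            sub = df[df["year"] == y].set_index("age")
            for g in groups:
                sel = [a for a in ages if g.contains(a)]
                if not sel:
                    raise ValidationError(f"grouping {g.label} covers no simulated age")
                n_pop = int(sub.loc[sel, "n_alive"].sum())
                n_care = int(sub.loc[sel, "n_ill"].sum())
                prev_rows.append((y, sex, g.lower, g.upper, n_care, max(n_pop, 1)))
            for a in ages:
                py = float(sub.loc[a, "person_years"])
                m = float(sub.loc[a, "deaths"]) / py if py > 0 else 0.0
                mort_rows.append((y, sex, int(a), m))
    prev = PrevalenceTable.from_records(
        pd.DataFrame(prev_rows, columns=["year", "sex", "age_lo", "age_hi", "n_care", "n_pop"])
    )
    mort = MortalityTable(
        pd.DataFrame(mort_rows, columns=["year", "sex", "age", "m"])
    )
    return prev, mort


def synthesize_tables(
    truths: Mapping[str, SyntheticTruth],
    years: Sequence[int] = (2011, 2013, 2015, 2017, 2019),
    ages: Sequence[int] = tuple(range(0, 100)),
    groups: Sequence[AgeGroup] = PFLEGESTATISTIK_GROUPS,
    step: float = 0.05,
    cohort_size: int = 1_000_000,
) -> tuple[PrevalenceTable, MortalityTable, dict[str, PrevalenceSurface]]:
    """Forward-solve every sex and emit one combined table pair.

    The surface is solved at the integer ages (for the mortality table) and
    at the half-integer midpoints of the single-year age classes (for the
    prevalence aggregation).
    """
    prev_parts, mort_parts, surfaces = [], [], {}
    solve_ages = np.union1d(np.asarray(ages, float), np.asarray(ages, float) + 0.5)
    for sex, truth in truths.items():
        surface = solve_prevalence_forward(truth, years, solve_ages, step=step)
        surfaces[sex] = surface
        prev, mort = emit_tables(surface, sex, years=years, groups=groups, cohort_size=cohort_size)
        prev_parts.append(prev.df)
        mort_parts.append(mort.df)
    prev = PrevalenceTable(pd.concat(prev_parts, ignore_index=True))
    mort = MortalityTable(pd.concat(mort_parts, ignore_index=True))
    return prev, mort, surfaces


# --------------------------------------------------------------------------
# recovery experiment
# --------------------------------------------------------------------------

SINGLE_AGE_GROUPS: tuple[AgeGroup, ...] = tuple(
    AgeGroup(a, a + 1) for a in range(0, 100)
)


@dataclass(frozen=True)
class RecoverySettings:
    """Pipeline settings of a parameter-recovery run.

    The default fit window keeps groups whose lower bound is >= min_fit_age
    (the broad childhood/adult groups are far from logit-linear and the
    reporting window is 50-90) and drops the open-ended top group, whose
    representative age is a convention rather than a measurement.
    """

    years: tuple[int, ...] = (2011, 2013, 2015, 2017, 2019)
    table_ages: tuple[int, ...] = tuple(range(0, 100))
    groups: tuple[AgeGroup, ...] = PFLEGESTATISTIK_GROUPS
    eval_year: int = 2015
    eval_ages: tuple[int, ...] = tuple(range(60, 86))
    min_fit_age: int = 40
    include_open_groups: bool = False
    weights: str = "none"
    step: float = 0.05
    cohort_size: int = 1_000_000


def recovery_experiment(
    truths: Mapping[str, SyntheticTruth],
    settings: RecoverySettings = RecoverySettings(),
) -> dict:
    """Run tables -> regression -> estimator and compare with the truth.

    Estimation uses the true R and r of each sex's generating process and
    the emitted (exact) mortality table.  Returns per-sex per-age relative
    errors of the recovered incidence plus max/mean summaries over the
    evaluation ages.
    """
    prev, mort, _surfaces = synthesize_tables(
        truths,
        years=settings.years,
        ages=settings.table_ages,
        groups=settings.groups,
        step=settings.step,
        cohort_size=settings.cohort_size,
    )
    options = FitOptions(
        include_groups=lambda g: g.lower >= settings.min_fit_age
        and (settings.include_open_groups or not g.is_open),
        weights=settings.weights,
    )
    report: dict = {"per_sex": {}, "settings": settings}
    max_rel = 0.0
    rel_all = []
    for sex, truth in truths.items():
        model = fit_logit_linear(prev, sex, options)
        config = ScenarioConfig(
            R=(truth.R,),
            r=truth.r,
            year=settings.eval_year,
            ages=tuple(float(a) for a in settings.eval_ages),
            sexes=(sex,),
        )
        inc = run_scenarios({sex: model}, mort, config).sorted()
        ages = inc["age"].to_numpy(float)
        est = inc["incidence_per_1000py"].to_numpy(float) / 1000.0
        true = np.asarray(truth.incidence(float(settings.eval_year), ages), dtype=float)
        rel = np.abs(est - true) / true
        report["per_sex"][sex] = {
            "model": model,
            "ages": ages,
            "i_true": true,
            "i_est": est,
            "rel_error": rel,
            "max_rel_error": float(rel.max()),
            "mean_rel_error": float(rel.mean()),
        }
        max_rel = max(max_rel, float(rel.max()))
        rel_all.append(rel)
    report["max_rel_error"] = max_rel
    report["mean_rel_error"] = float(np.mean(np.concatenate(rel_all)))
    return report
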