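"""Tabular containers for the pipeline: prevalence, mortality and incidence tables.

The containers are thin, validated wrappers around :class:`pandas.DataFrame`
so that real registry extracts (converted to the documented CSV schemas) and
synthetic tables are interchangeable everywhere downstream.

CSV schemas
-----------
prevalence : ``year,sex,age_lo,age_hi,n_care,n_pop[,prevalence]``
    ``age_hi`` blank means an open-ended top group (e.g. 90+).
mortality : ``year,sex,age,m``
    ``m`` is the all-cause mortality rate per person-year at a single age.
incidence : ``year,sex,age,R,r,incidence_per_1000py,flag``

All rates are per person-year internally; the x1000 scaling happens only in
the incidence output table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .errors import CoverageError, SchemaError, ValidationError

SEXES = ("female", "male")

#: German long-term-care statistics age grouping: <15, 15-59, then 5-year
#: steps from 60 to 89, and 90+ (open-ended).
PFLEGESTATISTIK_GROUPS: tuple["AgeGroup", ...]


@dataclass(frozen=True)
class AgeGroup:
    """Half-open age interval [lower, upper); ``upper=inf`` means open-ended."""

    lower: int
    upper: float  # math.inf for an open-ended top group

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ValidationError(f"age group lower bound must be >= 0, got {self.lower}")
        if not self.upper > self.lower:
            raise ValidationError(
                f"age group must satisfy lower < upper, got [{self.lower}, {self.upper})"
            )

    @property
    def is_open(self) -> bool:
        return math.isinf(self.upper)

    @property
    def label(self) -> str:
        if self.is_open:
            return f"{self.lower}+"
        return f"{self.lower}-{int(self.upper) - 1}"

    def contains(self, age: float) -> bool:
        return self.lower <= age < self.upper

    def midpoint(self) -> float:
        if self.is_open:
            raise ValidationError(f"open-ended group {self.label} has no midpoint")
        return 0.5 * (self.lower + self.upper)


PFLEGESTATISTIK_GROUPS = tuple(
    [AgeGroup(0, 15), AgeGroup(15, 60)]
    + [AgeGroup(lo, lo + 5) for lo in range(60, 90, 5)]
    + [AgeGroup(90, math.inf)]
)


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file is missing column(s): {', '.join(missing)}")


def _check_sexes(values: pd.Series, what: str) -> None:
    bad = sorted(set(values.astype(str)) - set(SEXES))
    if bad:
        raise ValidationError(f"{what}: unknown sex value(s) {bad}; expected {SEXES}")


@dataclass(frozen=True)
class PrevalenceTable:
    """Aggregated prevalence counts by calendar year, sex and age group.

    ``df`` columns: year (int), sex, age_lo (int), age_hi (float, inf for
    open-ended), n_care, n_pop, prevalence (recomputed from the counts).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        _require_columns(df, ["year", "sex", "age_lo", "age_hi", "n_care", "n_pop"], "prevalence")
        _check_sexes(df["sex"], "prevalence table")
        bad = df[(df["n_care"] < 0) | (df["n_care"] > df["n_pop"])]
        if not bad.empty:
            row = bad.iloc[0]
            raise ValidationError(
                "prevalence table requires 0 <= n_care <= n_pop; offending row: "
                f"year={row['year']} sex={row['sex']} age_lo={row['age_lo']} "
                f"n_care={row['n_care']} n_pop={row['n_pop']}"
            )
        if (df["n_pop"] <= 0).any():
            raise ValidationError("prevalence table contains rows with n_pop <= 0")
        # groups within one (year, sex) must be pairwise disjoint
        for (year, sex), sub in df.groupby(["year", "sex"]):
            intervals = sorted(zip(sub["age_lo"], sub["age_hi"]))
            for (lo1, hi1), (lo2, _hi2) in zip(intervals, intervals[1:]):
                if lo2 < hi1:
                    raise ValidationError(
                        f"overlapping age groups for year={year}, sex={sex}: "
                        f"[{lo1},{hi1}) and [{lo2},...)"
                    )

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].unique())

    def groups(self) -> list[AgeGroup]:
        uniq = {(int(lo), float(hi)) for lo, hi in zip(self.df["age_lo"], self.df["age_hi"])}
        return [AgeGroup(lo, hi) for lo, hi in sorted(uniq)]

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "PrevalenceTable":
        df = records.copy()
        df["prevalence"] = df["n_care"] / df["n_pop"]
        return cls(df.reset_index(drop=True))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PrevalenceTable":
        return read_prevalence_csv(path)

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out = out.sort_values(["year", "sex", "age_lo"]).reset_index(drop=True)
        out["age_hi"] = out["age_hi"].map(lambda h: "" if math.isinf(h) else int(h))
        out.to_csv(path, index=False, float_format="%.10g")


def read_prevalence_csv(path: str | Path) -> PrevalenceTable:
    """Read and validate a prevalence CSV.

    The prevalence column, if present, is recomputed from the counts; a
    discrepancy larger than 0.5/n_pop is reported as a warning because the
    counts are the primary data.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"prevalence file not found: {path}")
    df = pd.read_csv(path, dtype={"sex": str})
    _require_columns(df, ["year", "sex", "age_lo", "age_hi", "n_care", "n_pop"], "prevalence")
    df["age_hi"] = pd.to_numeric(df["age_hi"], errors="coerce").fillna(math.inf)
    for col in ("year", "age_lo", "n_care", "n_pop"):
        df[col] = pd.to_numeric(df[col])
    stated = df["prevalence"].copy() if "prevalence" in df.columns else None
    table = PrevalenceTable.from_records(
        df[["year", "sex", "age_lo", "age_hi", "n_care", "n_pop"]]
    )
    if stated is not None:
        recomputed = table.df["prevalence"].to_numpy()
        tol = 0.5 / table.df["n_pop"].to_numpy()
        off = np.abs(recomputed - pd.to_numeric(stated).to_numpy()) > tol
        if off.any():
            idx = int(np.argmax(off))
            warnings.warn(
                f"prevalence column disagrees with n_care/n_pop beyond 0.5/n_pop "
                f"in {int(off.sum())} row(s) (first: row {idx}); counts take precedence",
                stacklevel=2,
            )
    return table


@dataclass(frozen=True)
class MortalityTable:
    """All-cause mortality rate per person-year by year, sex and single age."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        _require_columns(df, ["year", "sex", "age", "m"], "mortality")
        _check_sexes(df["sex"], "mortality table")
        neg = df[df["m"] < 0]
        if not neg.empty:
            row = neg.iloc[0]
            raise ValidationError(
                f"negative mortality rate m={row['m']} at year={row['year']} "
                f"sex={row['sex']} age={row['age']}"
            )
        dup = df.duplicated(subset=["year", "sex", "age"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValidationError(
                f"duplicate (year, sex, age) key: ({row['year']}, {row['sex']}, {row['age']})"
            )
        for (year, sex), sub in df.groupby(["year", "sex"]):
            ages = np.sort(sub["age"].to_numpy())
            if len(ages) > 1 and not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
                raise ValidationError(
                    f"ages are not contiguous for year={year}, sex={sex}"
                )
        object.__setattr__(self, "_interp_cache", {})

    @classmethod
    def from_csv(cls, path: str | Path) -> "MortalityTable":
        return read_mortality_csv(path)

    def to_csv(self, path: str | Path) -> None:
        out = self.df.sort_values(["year", "sex", "age"]).reset_index(drop=True)
        out.to_csv(path, index=False, float_format="%.10g")

    def _grid(self, sex: str):
        cache: dict = self._interp_cache  # type: ignore[attr-defined]
        if sex in cache:
            return cache[sex]
        sub = self.df[self.df["sex"] == sex]
        if sub.empty:
            raise CoverageError(f"mortality table has no rows for sex={sex!r}")
        years = np.sort(sub["year"].unique())
        ages = np.sort(sub["age"].unique())
        pivot = sub.pivot(index="year", columns="age", values="m")
        pivot = pivot.reindex(index=years, columns=ages)
        if pivot.isna().any().any():
            raise CoverageError(
                f"mortality table for sex={sex!r} is not a full year x age grid; "
                "bilinear interpolation requires a rectangular table"
            )
        values = pivot.to_numpy(float)
        yrs, ags = years.astype(float), ages.astype(float)
        if len(yrs) == 1 or len(ags) == 1:
            # degenerate axis: linear interpolation along the other one,
            # exact-match required along the singleton axis
            def interp(pts, _yrs=yrs, _ags=ags, _v=values):
                pts = np.atleast_2d(pts)
                y, a = pts[..., 0], pts[..., 1]
                if len(_yrs) == 1:
                    if np.any(y != _yrs[0]):
                        raise ValueError(f"year outside tabulated range [{_yrs[0]}, {_yrs[0]}]")
                    if np.any((a < _ags[0]) | (a > _ags[-1])):
                        raise ValueError(f"age outside tabulated range [{_ags[0]}, {_ags[-1]}]")
                    return np.interp(a, _ags, _v[0, :])
                if np.any(a != _ags[0]):
                    raise ValueError(f"age outside tabulated range [{_ags[0]}, {_ags[0]}]")
                if np.any((y < _yrs[0]) | (y > _yrs[-1])):
                    raise ValueError(f"year outside tabulated range [{_yrs[0]}, {_yrs[-1]}]")
                return np.interp(y, _yrs, _v[:, 0])
        else:
            interp = RegularGridInterpolator(
                (yrs, ags), values, method="linear", bounds_error=True
            )
        cache[sex] = interp
        return interp

    def rate(self, year, age, sex: str):
        """Bilinear interpolation of m in (year, age) for one sex.

        Exact at tabulated points; queries outside the tabulated hull raise
        :class:`CoverageError` rather than extrapolating.
        """
        interp = self._grid(sex)
        year = np.asarray(year, dtype=float)
        age = np.asarray(age, dtype=float)
        pts = np.stack(np.broadcast_arrays(year, age), axis=-1)
        try:
            out = interp(pts)
        except ValueError as exc:
            raise CoverageError(
                f"mortality query outside tabulated range for sex={sex!r}: {exc}"
            ) from None
        out = np.asarray(out)
        if np.isscalar(year) or year.ndim == 0:
            return float(out.ravel()[0])
        return out.reshape(np.broadcast_shapes(year.shape, age.shape))


def mortality_at(table: MortalityTable, year, age, sex: str):
    """Functional alias for :meth:`MortalityTable.rate`."""
    return table.rate(year, age, sex)


def read_mortality_csv(path: str | Path) -> MortalityTable:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"mortality file not found: {path}")
    df = pd.read_csv(path, dtype={"sex": str})
    _require_columns(df, ["year", "sex", "age", "m"], "mortality")
    for col in ("year", "age"):
        df[col] = pd.to_numeric(df[col], downcast="integer")
    df["m"] = pd.to_numeric(df["m"])
    return MortalityTable(df.reset_index(drop=True))


INCIDENCE_COLUMNS = ["year", "sex", "age", "R", "r", "incidence_per_1000py", "flag"]

FLAG_OK = "ok"
FLAG_NEGATIVE = "negative_estimate"


@dataclass(frozen=True)
class IncidenceTable:
    """Estimated incidence per 1000 person-years, one row per (sex, age, R)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.df, INCIDENCE_COLUMNS, "incidence")
        neg = self.df["incidence_per_1000py"] < 0
        flagged = self.df["flag"] == FLAG_NEGATIVE
        if not (neg == flagged).all():
            raise ValidationError(
                "flag must be 'negative_estimate' exactly when incidence < 0"
            )

    def sorted(self) -> pd.DataFrame:
        return (
            self.df[INCIDENCE_COLUMNS]
            .sort_values(["sex", "age", "R"])
            .reset_index(drop=True)
        )

    def to_csv(self, path: str | Path) -> None:
        write_incidence_csv(self, path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "IncidenceTable":
        df = pd.read_csv(Path(path), dtype={"sex": str, "flag": str})
        return cls(df)


def write_incidence_csv(table: IncidenceTable, path: str | Path) -> None:
    """Write an incidence table with deterministic column and row order."""
    if table.df.empty:
        raise ValidationError("refusing to write an empty incidence table")
    table.sorted().to_csv(Path(path), index=False, float_format="%.6g")
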