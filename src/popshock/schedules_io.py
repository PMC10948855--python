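"""Demographic input tables: containers, validation, and delimited-text I/O.

The containers hold single-year-of-age demographic schedules in the shape of
standard medium-variant projection extracts: central death rates m(x) by
calendar year, age 0..100 (100 meaning the open interval 100+) and sex;
age-specific fertility rates by year and single year of reproductive age;
total annual net migration counts; and the sex ratio at birth per year.
All tables are dense numpy arrays over a contiguous year range, which makes
validation (completeness, contiguity) a property of construction rather than
a per-lookup concern.

File dialect: comma-separated UTF-8 text with a header row, "." decimal
point, lowercase sex codes ``female``/``male``. Values are written with 17
significant digits so a write/read round trip is an exact identity on
float64 data.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AGE_MAX = 100
AGES = np.arange(AGE_MAX + 1)
SEXES = ("female", "male")
FEMALE, MALE = 0, 1

_FLOAT_FMT = "%.17g"


class TableFormatError(ValueError):
    """A file does not have the expected columns or cannot be parsed."""


class TableValidationError(ValueError):
    """Table contents violate a domain invariant."""


class CoverageError(KeyError):
    """A requested year is outside the table's year range."""


def _require_contiguous_years(years: np.ndarray) -> np.ndarray:
    years = np.asarray(years, dtype=np.int64)
    if years.ndim != 1 or years.size == 0:
        raise TableValidationError("year range is empty")
    if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
        raise TableValidationError(
            f"years not contiguous: {years.min()}..{years.max()} with gaps"
        )
    return years


def _year_index(years: np.ndarray, year: int, what: str) -> int:
    if year < years[0] or year > years[-1]:
        raise CoverageError(f"{what}: year {year} outside range {years[0]}..{years[-1]}")
    return int(year - years[0])


@dataclasses.dataclass
class MortalityTable:
    """Central death rates m(x), deaths per person-year, by year, age and sex.

    ``rates`` has shape (n_years, 101, 2); axis order (year, age, sex) with
    sex 0 = female, 1 = male, and age 100 the open interval 100+.
    """

    years: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.years = _require_contiguous_years(self.years)
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if self.rates.shape != (self.years.size, AGE_MAX + 1, 2):
            raise TableValidationError(
                f"mortality rates shape {self.rates.shape} != "
                f"({self.years.size}, {AGE_MAX + 1}, 2)"
            )

    def validate(self) -> "MortalityTable":
        bad = ~np.isfinite(self.rates)
        if bad.any():
            y, a, s = map(int, np.argwhere(bad)[0])
            raise TableValidationError(
                f"non-finite rate at (year={self.years[y]}, age={a}, sex={SEXES[s]})"
            )
        neg = self.rates < 0
        if neg.any():
            y, a, s = map(int, np.argwhere(neg)[0])
            raise TableValidationError(
                f"negative rate at (year={self.years[y]}, age={a}, sex={SEXES[s]})"
            )
        return self

    def rates_for(self, year: int) -> np.ndarray:
        """(101, 2) view of the rates in ``year``."""
        return self.rates[_year_index(self.years, year, "mortality")]

    def loc(self, year: int, age: int, sex: str) -> float:
        return float(self.rates_for(year)[age, SEXES.index(sex)])

    def copy(self) -> "MortalityTable":
        return MortalityTable(self.years.copy(), self.rates.copy())

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product(
            [self.years, AGES, SEXES], names=["year", "age", "sex"]
        )
        return pd.DataFrame({"mx": self.rates.ravel()}, index=idx).reset_index()


@dataclasses.dataclass
class FertilityTable:
    """Age-specific fertility rates, live births per woman-year.

    ``rates`` has shape (n_years, n_ages) over the contiguous reproductive
    age range ``ages`` (default 15..49).
    """

    years: np.ndarray
    ages: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.years = _require_contiguous_years(self.years)
        self.ages = np.asarray(self.ages, dtype=np.int64)
        if not np.array_equal(self.ages, np.arange(self.ages[0], self.ages[-1] + 1)):
            raise TableValidationError("fertility ages not contiguous")
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if self.rates.shape != (self.years.size, self.ages.size):
            raise TableValidationError(
                f"fertility rates shape {self.rates.shape} != "
                f"({self.years.size}, {self.ages.size})"
            )

    def validate(self) -> "FertilityTable":
        if not np.isfinite(self.rates).all():
            y, a = map(int, np.argwhere(~np.isfinite(self.rates))[0])
            raise TableValidationError(
                f"non-finite rate at (year={self.years[y]}, age={self.ages[a]})"
            )
        if (self.rates < 0).any():
            y, a = map(int, np.argwhere(self.rates < 0)[0])
            raise TableValidationError(
                f"negative rate at (year={self.years[y]}, age={self.ages[a]})"
            )
        tfr = self.rates.sum(axis=1)
        if (tfr <= 0).any():
            y = int(np.flatnonzero(tfr <= 0)[0])
            raise TableValidationError(f"TFR not positive in year {self.years[y]}")
        return self

    def rates_for(self, year: int) -> np.ndarray:
        return self.rates[_year_index(self.years, year, "fertility")]

    def tfr(self, year: int) -> float:
        """Total fertility rate: the sum of single-year age-specific rates."""
        return float(self.rates_for(year).sum())

    def copy(self) -> "FertilityTable":
        return FertilityTable(self.years.copy(), self.ages.copy(), self.rates.copy())

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product([self.years, self.ages], names=["year", "age"])
        return pd.DataFrame({"asfr": self.rates.ravel()}, index=idx).reset_index()


@dataclasses.dataclass
class MigrationSeries:
    """Total annual net migration counts (persons; may be negative)."""

    years: np.ndarray
    totals: np.ndarray

    def __post_init__(self) -> None:
        self.years = _require_contiguous_years(self.years)
        self.totals = np.asarray(self.totals, dtype=np.float64)
        if self.totals.shape != (self.years.size,):
            raise TableValidationError("migration totals must be one value per year")

    def validate(self) -> "MigrationSeries":
        if not np.isfinite(self.totals).all():
            y = int(np.flatnonzero(~np.isfinite(self.totals))[0])
            raise TableValidationError(f"non-finite net migration in year {self.years[y]}")
        return self

    def total_for(self, year: int) -> float:
        return float(self.totals[_year_index(self.years, year, "migration")])

    def copy(self) -> "MigrationSeries":
        return MigrationSeries(self.years.copy(), self.totals.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "net_migration": self.totals})


@dataclasses.dataclass
class SRBSeries:
    """Sex ratio at birth: male live births per female live birth, per year."""

    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = _require_contiguous_years(self.years)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.years.size,):
            raise TableValidationError("SRB must be one value per year")

    def validate(self) -> "SRBSeries":
        bad = ~(np.isfinite(self.values) & (self.values > 0))
        if bad.any():
            y = int(np.flatnonzero(bad)[0])
            raise TableValidationError(f"SRB not positive/finite in year {self.years[y]}")
        return self

    def srb_for(self, year: int) -> float:
        return float(self.values[_year_index(self.years, year, "srb")])

    def copy(self) -> "SRBSeries":
        return SRBSeries(self.years.copy(), self.values.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "srb": self.values})


@dataclasses.dataclass
class PopulationState:
    """Population counts by single year of age and sex on 1 January of ``year``.

    ``counts`` has shape (101, 2); age 100 is the open interval 100+.
    Counts are non-negative reals in deterministic mode and integer-valued
    in stochastic mode.
    """

    year: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.year = int(self.year)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (AGE_MAX + 1, 2):
            raise TableValidationError(
                f"population counts shape {self.counts.shape} != ({AGE_MAX + 1}, 2)"
            )

    def validate(self) -> "PopulationState":
        bad = ~(np.isfinite(self.counts) & (self.counts >= 0))
        if bad.any():
            a, s = map(int, np.argwhere(bad)[0])
            raise TableValidationError(
                f"invalid count at (year={self.year}, age={a}, sex={SEXES[s]})"
            )
        return self

    def total(self) -> float:
        return float(self.counts.sum())

    def is_integer(self) -> bool:
        return bool(np.array_equal(self.counts, np.rint(self.counts)))

    def copy(self) -> "PopulationState":
        return PopulationState(self.year, self.counts.copy())

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product(
            [[self.year], AGES, SEXES], names=["year", "age", "sex"]
        )
        return pd.DataFrame({"count": self.counts.ravel()}, index=idx).reset_index()


@dataclasses.dataclass
class RateSchedules:
    """One scenario's demographic inputs, bundled.

    Mortality, fertility, net migration and sex ratio at birth for a single
    scenario (e.g. "baseline" or "counterfactual"). ``validate`` checks each
    component and that all four cover a common, contiguous year range.
    """

    mortality: MortalityTable
    fertility: FertilityTable
    migration: MigrationSeries
    srb: SRBSeries
    label: str = "scenario"

    def validate(self) -> "RateSchedules":
        self.mortality.validate()
        self.fertility.validate()
        self.migration.validate()
        self.srb.validate()
        return self

    @property
    def years(self) -> np.ndarray:
        """Years covered by all four components."""
        lo = max(t.years[0] for t in (self.mortality, self.fertility, self.migration, self.srb))
        hi = min(t.years[-1] for t in (self.mortality, self.fertility, self.migration, self.srb))
        return np.arange(lo, hi + 1)

    def covers(self, year: int) -> bool:
        ys = self.years
        return bool(ys.size) and ys[0] <= year <= ys[-1]

    def copy(self) -> "RateSchedules":
        return RateSchedules(
            self.mortality.copy(),
            self.fertility.copy(),
            self.migration.copy(),
            self.srb.copy(),
            self.label,
        )


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = {
    "mortality": ["year", "age", "sex", "mx"],
    "fertility": ["year", "age", "asfr"],
    "migration": ["year", "net_migration"],
    "srb": ["year", "srb"],
    "population": ["year", "age", "sex", "count"],
}

_VALUE_COLUMN = {
    "mortality": "mx",
    "fertility": "asfr",
    "migration": "net_migration",
    "srb": "srb",
    "population": "count",
}


def _parse_numeric(df: pd.DataFrame, col: str, path: Path) -> pd.Series:
    # numpy's string parser is correctly rounded, so the written 17-digit
    # representation reads back to the identical float64
    raw = df[col].to_numpy()
    try:
        return pd.Series(raw.astype(np.float64), index=df.index)
    except (ValueError, TypeError):
        for i, v in enumerate(raw):
            try:
                float(v)
            except (ValueError, TypeError):
                # +2: header line plus 1-based numbering
                raise TableFormatError(
                    f"{path}: non-numeric value {v!r} in column '{col}' at line {i + 2}"
                ) from None
        raise


def _check_complete_ages(df: pd.DataFrame, ages: np.ndarray, path: Path) -> None:
    expected = set(ages.tolist())
    for (year, sex), grp in df.groupby(["year", "sex"], sort=True):
        got = set(grp["age"].tolist())
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            detail = f"missing ages {missing[:5]}" if missing else f"unexpected ages {extra[:5]}"
            raise TableValidationError(
                f"{path}: ages not contiguous for (year={year}, sex={sex}): {detail}"
            )
        if grp["age"].duplicated().any():
            raise TableValidationError(f"{path}: duplicate age rows for (year={year}, sex={sex})")


def read_rate_table(path, kind: str):
    """Read one demographic table from a CSV file.

    ``kind`` selects the expected layout: ``mortality`` (year,age,sex,mx),
    ``fertility`` (year,age,asfr), ``migration`` (year,net_migration),
    ``srb`` (year,srb) or ``population`` (year,age,sex,count). Unknown
    columns are ignored with a warning. Returns the validated container;
    for ``population`` a single :class:`PopulationState` (or a list of them,
    sorted by year, when the file holds several years).
    """
    path = Path(path)
    if kind not in _REQUIRED_COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}")
    required = _REQUIRED_COLUMNS[kind]
    df = pd.read_csv(path, dtype=str, keep_default_na=False).replace({"": None})
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise TableFormatError(f"{path}: missing required column '{missing_cols[0]}'")
    unknown = [c for c in df.columns if c not in required]
    if unknown:
        logger.warning("%s: ignoring unknown columns %s", path, unknown)
    df = df[required].copy()

    for col in ("year", "age"):
        if col in required:
            vals = _parse_numeric(df, col, path)
            if not np.array_equal(vals, np.rint(vals)):
                raise TableFormatError(f"{path}: column '{col}' must be integer")
            df[col] = vals.astype(np.int64)
    value_col = _VALUE_COLUMN[kind]
    df[value_col] = _parse_numeric(df, value_col, path)
    if "sex" in required:
        bad_sex = ~df["sex"].isin(SEXES)
        if bad_sex.any():
            raise TableFormatError(
                f"{path}: unknown sex code {df['sex'][bad_sex.idxmax()]!r} "
                f"(expected 'female'/'male')"
            )

    if kind == "mortality":
        _check_complete_ages(df, AGES, path)
        years = _require_contiguous_years(np.sort(df["year"].unique()))
        rates = (
            df.assign(sex_i=df["sex"].map({s: i for i, s in enumerate(SEXES)}))
            .sort_values(["year", "age", "sex_i"])["mx"]
            .to_numpy()
            .reshape(years.size, AGE_MAX + 1, 2)
        )
        return MortalityTable(years, rates).validate()
    if kind == "fertility":
        ages = np.sort(df["age"].unique())
        per_year = df.groupby("year")["age"].apply(lambda a: tuple(sorted(a)))
        if per_year.nunique() != 1:
            raise TableValidationError(f"{path}: reproductive age range differs across years")
        years = _require_contiguous_years(np.sort(df["year"].unique()))
        rates = (
            df.sort_values(["year", "age"])["asfr"].to_numpy().reshape(years.size, ages.size)
        )
        return FertilityTable(years, ages, rates).validate()
    if kind == "migration":
        dfs = df.sort_values("year")
        if dfs["year"].duplicated().any():
            raise TableValidationError(f"{path}: duplicate year rows")
        return MigrationSeries(dfs["year"].to_numpy(), dfs["net_migration"].to_numpy()).validate()
    if kind == "srb":
        dfs = df.sort_values("year")
        if dfs["year"].duplicated().any():
            raise TableValidationError(f"{path}: duplicate year rows")
        return SRBSeries(dfs["year"].to_numpy(), dfs["srb"].to_numpy()).validate()
    # population
    _check_complete_ages(df, AGES, path)
    states = []
    for year, grp in df.groupby("year", sort=True):
        counts = (
            grp.assign(sex_i=grp["sex"].map({s: i for i, s in enumerate(SEXES)}))
            .sort_values(["age", "sex_i"])["count"]
            .to_numpy()
            .reshape(AGE_MAX + 1, 2)
        )
        states.append(PopulationState(int(year), counts).validate())
    return states[0] if len(states) == 1 else states


def write_table(table, path) -> None:
    """Write a table (or a list of PopulationStates) as canonical CSV.

    Column order is (year, age, sex, value) as applicable; rows sort by
    year, then age, then female before male, so identical tables produce
    identical bytes.
    """
    path = Path(path)
    if isinstance(table, list):
        frames = [s.to_frame() for s in sorted(table, key=lambda s: s.year)]
        df = pd.concat(frames, ignore_index=True)
    else:
        df = table.to_frame()
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
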