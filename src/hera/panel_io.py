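"""Panel data model and CSV I/O for city-level health resource data.

A *resource panel* is a balanced city x year table of health resource and
activity indicators (institutions, beds, health workers, finance, service
outputs) together with each city's population, land area and region group.
The canonical exchange format is a long-format CSV, one record per row:

    city,year,region,population_thousand,area_km2,institutions,beds,
    health_workers,gov_subsidy_bn,total_expenditure_bn,outpatient_10k,
    hosp_rate_pct,general_income_bn

Population is stored in *thousands of persons* so that ``resource /
population`` is directly a per-1000-person density; area is in km².
Thousands separators ("491,522") are tolerated on read, never written.
The panel must be balanced (every city observed in every year) because the
yearly efficiency frontiers and adjacent-period productivity comparisons
both assume a constant set of decision-making units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HeraError",
    "PanelSchemaError",
    "DuplicateRecordError",
    "UnbalancedPanelError",
    "PanelValidationError",
    "PanelLookupError",
    "CityYearRecord",
    "RegionScheme",
    "ResourcePanel",
    "JIANGSU_SCHEME",
    "INDICATOR_FIELDS",
    "CSV_COLUMNS",
    "read_panel",
    "write_panel",
    "derive_density",
    "province_density",
]


class HeraError(Exception):
    """Base class for all package errors."""


class PanelSchemaError(HeraError):
    """The CSV header is missing or misnames a canonical column."""


class DuplicateRecordError(HeraError):
    """A (city, year) pair appears more than once."""


class UnbalancedPanelError(HeraError):
    """Some city lacks a record for some year of the panel."""

    def __init__(self, missing: Sequence[tuple[str, int]]):
        self.missing = list(missing)
        pairs = ", ".join(f"({c}, {y})" for c, y in self.missing[:10])
        more = "" if len(self.missing) <= 10 else f" (+{len(self.missing) - 10} more)"
        super().__init__(f"unbalanced panel; missing (city, year) pairs: {pairs}{more}")


class PanelValidationError(HeraError):
    """A record violates a field invariant (sign, range, region membership)."""


class PanelLookupError(HeraError, LookupError):
    """Unknown field name, year or city requested from a panel."""


# Indicator fields, in canonical order.  The first five are the resource
# (input) indicators, the last three the activity (output) indicators.
INDICATOR_FIELDS: tuple[str, ...] = (
    "institutions",
    "beds",
    "health_workers",
    "gov_subsidy",
    "total_expenditure",
    "outpatient_volume",
    "hospitalization_rate",
    "general_income",
)

# CSV column name -> record field name (canonical dialect, case-insensitive).
CSV_COLUMNS: dict[str, str] = {
    "city": "city",
    "year": "year",
    "region": "region",
    "population_thousand": "population",
    "area_km2": "area",
    "institutions": "institutions",
    "beds": "beds",
    "health_workers": "health_workers",
    "gov_subsidy_bn": "gov_subsidy",
    "total_expenditure_bn": "total_expenditure",
    "outpatient_10k": "outpatient_volume",
    "hosp_rate_pct": "hospitalization_rate",
    "general_income_bn": "general_income",
}
_FIELD_TO_COLUMN = {v: k for k, v in CSV_COLUMNS.items()}


@dataclass(frozen=True)
class CityYearRecord:
    """One city observed in one calendar year.

    population: thousands of persons (> 0); area: km² (> 0); institutions,
    beds, health_workers: counts; gov_subsidy, total_expenditure,
    general_income: billions of currency; outpatient_volume: ten-thousand
    visits; hospitalization_rate: percent in [0, 100].
    """

    city: str
    year: int
    region: str
    population: float
    area: float
    institutions: float = 0.0
    beds: float = 0.0
    health_workers: float = 0.0
    gov_subsidy: float = 0.0
    total_expenditure: float = 0.0
    outpatient_volume: float = 0.0
    hospitalization_rate: float = 0.0
    general_income: float = 0.0

    def __post_init__(self) -> None:
        where = f"record ({self.city!r}, {self.year})"
        if not self.population > 0:
            raise PanelValidationError(f"{where}: population must be > 0, got {self.population}")
        if not self.area > 0:
            raise PanelValidationError(f"{where}: area must be > 0, got {self.area}")
        for name in INDICATOR_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise PanelValidationError(f"{where}: {name} must be finite and >= 0, got {v}")
        if not 0.0 <= self.hospitalization_rate <= 100.0:
            raise PanelValidationError(
                f"{where}: hospitalization_rate must lie in [0, 100], "
                f"got {self.hospitalization_rate}"
            )


@dataclass(frozen=True)
class RegionScheme:
    """A named partition of the city set into region groups."""

    name: str
    groups: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for g, cities in self.groups.items():
            for c in cities:
                if c in seen:
                    raise PanelValidationError(
                        f"region scheme {self.name!r}: city {c!r} assigned to both "
                        f"{seen[c]!r} and {g!r}"
                    )
                seen[c] = g
        object.__setattr__(self, "_city_to_group", seen)

    def group_of(self, city: str) -> str:
        try:
            return self._city_to_group[city]  # type: ignore[attr-defined]
        except KeyError:
            raise PanelLookupError(
                f"city {city!r} not covered by region scheme {self.name!r}"
            ) from None

    @property
    def cities(self) -> frozenset[str]:
        return frozenset(self._city_to_group)  # type: ignore[attr-defined]


#: The three-zone grouping of Jiangsu's 13 prefecture-level cities used as the
#: default region scheme: economically developed south, moderately developed
#: middle, less economically active north.
JIANGSU_SCHEME = RegionScheme(
    name="jiangsu-3-zone",
    groups={
        "south": frozenset({"Nanjing", "Zhenjiang", "Suzhou", "Wuxi", "Changzhou"}),
        "middle": frozenset({"Yangzhou", "Taizhou", "Nantong"}),
        "north": frozenset({"Xuzhou", "Lianyungang", "Suqian", "Huaian", "Yancheng"}),
    },
)


@dataclass
class ResourcePanel:
    """A validated, balanced collection of :class:`CityYearRecord`."""

    records: list[CityYearRecord]
    scheme_name: str = "from-records"

    years: tuple[int, ...] = field(init=False)
    cities: tuple[str, ...] = field(init=False)
    region_scheme: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int], CityYearRecord] = {}
        for r in self.records:
            key = (r.city, r.year)
            if key in seen:
                raise DuplicateRecordError(f"duplicate record for (city, year) = {key}")
            seen[key] = r
        self.years = tuple(sorted({r.year for r in self.records}))
        self.cities = tuple(sorted({r.city for r in self.records}))
        missing = [
            (c, y) for c in self.cities for y in self.years if (c, y) not in seen
        ]
        if missing:
            raise UnbalancedPanelError(missing)
        region_of: dict[str, str] = {}
        for r in self.records:
            if region_of.setdefault(r.city, r.region) != r.region:
                raise PanelValidationError(
                    f"city {r.city!r} assigned to multiple regions: "
                    f"{region_of[r.city]!r} and {r.region!r}"
                )
        self.region_scheme = region_of
        self._by_key = seen

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.region_scheme.values())))

    def record(self, city: str, year: int) -> CityYearRecord:
        try:
            return self._by_key[(city, year)]
        except KeyError:
            raise PanelLookupError(f"no record for (city, year) = ({city!r}, {year})") from None

    def year_slice(self, year: int) -> list[CityYearRecord]:
        if year not in self.years:
            raise PanelLookupError(f"year {year} not in panel (years: {self.years})")
        return [self._by_key[(c, year)] for c in self.cities]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cities:
            for y in self.years:
                r = self._by_key[(c, y)]
                rows.append({col: getattr(r, f) for col, f in CSV_COLUMNS.items()})
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scheme: RegionScheme | None = None,
                   scheme_name: str | None = None) -> "ResourcePanel":
        records = []
        for row in df.itertuples(index=False):
            d = {CSV_COLUMNS[c]: getattr(row, c) for c in df.columns}
            d["city"] = str(d["city"])
            d["year"] = int(d["year"])
            if scheme is not None:
                d["region"] = scheme.group_of(d["city"])
            else:
                d["region"] = str(d["region"])
            records.append(CityYearRecord(**d))
        name = scheme_name or (scheme.name if scheme is not None else "from-records")
        return cls(records, scheme_name=name)


def read_panel(path: str | Path, scheme: RegionScheme | None = None) -> ResourcePanel:
    """Read a panel CSV, validate it, and attach the region grouping.

    Column matching is case-insensitive; thousands separators in numeric
    fields are tolerated.  When *scheme* is given it overrides the CSV's
    ``region`` column (every city must then be covered by the scheme);
    otherwise the ``region`` column is used as-is.

    Raises :class:`PanelSchemaError` for a missing column,
    :class:`DuplicateRecordError` for a repeated (city, year) pair,
    :class:`UnbalancedPanelError` listing the missing pairs of an unbalanced
    panel, and :class:`PanelValidationError` for out-of-range values.
    """
    path = Path(path)
    if not path.exists():
        raise PanelSchemaError(f"panel file not found: {path}")
    try:
        df = pd.read_csv(path, thousands=",", dtype={0: str}, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise PanelSchemaError(f"cannot parse CSV {path}: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = set(CSV_COLUMNS)
    if scheme is not None:
        required -= {"region"}
    missing_cols = sorted(required - set(df.columns))
    if missing_cols:
        raise PanelSchemaError(
            f"{path}: missing required column(s): {', '.join(missing_cols)}"
        )
    if "region" not in df.columns:
        df["region"] = ""
    for col in CSV_COLUMNS:
        if col in ("city", "region"):
            df[col] = df[col].astype(str)
        elif df[col].dtype == object:
            # quoted numbers with separators that the tokenizer left as text
            try:
                df[col] = pd.to_numeric(
                    df[col].astype(str).str.replace(",", "", regex=False)
                )
            except (ValueError, TypeError) as exc:
                raise PanelValidationError(
                    f"{path}: non-numeric value in column {col!r}: {exc}"
                ) from exc
    return ResourcePanel.from_frame(df[list(CSV_COLUMNS)], scheme=scheme)


def write_panel(panel: ResourcePanel, path: str | Path) -> None:
    """Write a panel in the canonical CSV dialect (no thousands separators)."""
    panel.to_frame().to_csv(path, index=False)


def _basis_values(records: Iterable[CityYearRecord], basis: str) -> np.ndarray:
    if basis == "population":
        return np.array([r.population for r in records], dtype=float)
    if basis == "area":
        return np.array([r.area for r in records], dtype=float)
    raise PanelLookupError(f"unknown basis {basis!r}; expected 'population' or 'area'")


def derive_density(
    panel: ResourcePanel, resource: str, basis: str, year: int
) -> pd.Series:
    """Per-city resource density for one year.

    With ``basis='population'`` the result is the resource amount per 1000
    persons (resource / population-in-thousands); with ``basis='area'`` it is
    the amount per km².  Returns a Series indexed by city.
    """
    if resource not in INDICATOR_FIELDS:
        raise PanelLookupError(
            f"unknown resource field {resource!r}; expected one of {INDICATOR_FIELDS}"
        )
    recs = panel.year_slice(year)
    values = np.array([getattr(r, resource) for r in recs], dtype=float)
    base = _basis_values(recs, basis)
    return pd.Series(values / base, index=list(panel.cities), name=f"{resource}_per_{basis}")


def province_density(
    panel: ResourcePanel, resource: str, basis: str, year: int
) -> float:
    """Province-level density: total resource over total basis.

    This is the correct aggregate — not the mean of city densities, which
    would weight small and large cities equally.
    """
    if resource not in INDICATOR_FIELDS:
        raise PanelLookupError(
            f"unknown resource field {resource!r}; expected one of {INDICATOR_FIELDS}"
        )
    recs = panel.year_slice(year)
    total = float(sum(getattr(r, resource) for r in recs))
    base = float(_basis_values(recs, basis).sum())
    return total / base
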