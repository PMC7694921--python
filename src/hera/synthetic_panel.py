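"""Synthetic city-year panels with known inequality structure and a known
production technology.

Two generators:

* :func:`generate_panel` draws a balanced panel emulating a 13-city,
  3-region, 5-year provincial panel: log-normal city sizes, per-capita
  resource rates with region-level multipliers (controlling how much of the
  inequality is between regions), log-normal within-region dispersion, and
  smooth multiplicative yearly growth.  Under the defaults, inter-region
  differences dominate for beds/workers/finance while institutions are
  near-equally spread per capita — the qualitative regime of a developed
  coastal province with a richer south.
* :func:`generate_frontier_panel` overwrites the activity (output)
  indicators with a known Cobb–Douglas production frontier
  ``F(x) = A0 · g^(year−y0) · Π x_i^{β_i}`` shifted Hicks-neutrally by the
  factor *g* each year, times a half-normal inefficiency draw
  ``exp(−u), u ~ |N(0, σ_u²)|`` — giving every efficiency and productivity
  estimator a ground truth to recover.

Both are deterministic given their seed; each resource draws from its own
fixed sub-stream, so adding a resource never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_io import (
    CityYearRecord,
    HeraError,
    INDICATOR_FIELDS,
    ResourcePanel,
)

__all__ = [
    "ConfigError",
    "ResourceGen",
    "PanelGenConfig",
    "FrontierGenConfig",
    "TruthRecord",
    "generate_panel",
    "generate_frontier_panel",
]


class ConfigError(HeraError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class ResourceGen:
    """Generative settings for one indicator.

    base_rate: per-capita rate (resource units per thousand persons) in the
    first year — or the plain level when ``per_capita`` is False.  growth:
    multiplicative factor per year.  multipliers: region → relative level
    (drives the between-region share of inequality).  cv: log-normal sigma of
    the persistent city effect; year-to-year noise uses cv/4.
    """

    base_rate: float
    growth: float = 1.0
    multipliers: Mapping[str, float] = field(default_factory=dict)
    cv: float = 0.1
    integer: bool = False
    per_capita: bool = True
    clip: tuple[float, float] | None = None


def _default_resources() -> dict[str, ResourceGen]:
    south_heavy = {"south": 1.35, "middle": 1.0, "north": 0.72}
    return {
        # institutions spread nearly per-capita-evenly, slightly denser in the
        # north -> within-region dispersion dominates its Theil decomposition
        "institutions": ResourceGen(0.40, 1.005, {"south": 0.95, "middle": 1.0, "north": 1.08},
                                    cv=0.20, integer=True),
        "beds": ResourceGen(4.93, 1.055, dict(south_heavy), cv=0.08, integer=True),
        "health_workers": ResourceGen(7.41, 1.055, dict(south_heavy), cv=0.08, integer=True),
        # finance concentrates strongly in the developed south
        "gov_subsidy": ResourceGen(2.55e-4, 1.164, {"south": 1.9, "middle": 0.9, "north": 0.5},
                                   cv=0.15),
        "total_expenditure": ResourceGen(2.0e-3, 1.10, {"south": 1.5, "middle": 0.95, "north": 0.65},
                                         cv=0.12),
        "outpatient_volume": ResourceGen(0.55, 1.03, {"south": 1.2, "middle": 1.0, "north": 0.85},
                                         cv=0.10),
        "hospitalization_rate": ResourceGen(13.3, 1.005, {"south": 1.0, "middle": 1.0, "north": 1.05},
                                            cv=0.05, per_capita=False, clip=(0.0, 100.0)),
        "general_income": ResourceGen(1.9e-3, 1.11, {"south": 1.4, "middle": 1.0, "north": 0.7},
                                      cv=0.12),
    }


#: fixed sub-stream index per draw purpose (stable across releases)
_STREAMS = {name: i for i, name in enumerate(INDICATOR_FIELDS)}
_STREAMS["population"] = 100
_STREAMS["area"] = 101
_FRONTIER_STREAM = 999


@dataclass(frozen=True)
class PanelGenConfig:
    """Study conditions for the synthetic provincial panel: 13 cities in 3
    zones (5 south / 3 middle / 5 north) over 2014–2018, city populations and
    areas log-normal around provincial magnitudes (thousands of persons,
    km²)."""

    region_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"south": 5, "middle": 3, "north": 5}
    )
    years: tuple[int, ...] = (2014, 2015, 2016, 2017, 2018)
    pop_mean: Mapping[str, float] = field(
        default_factory=lambda: {"south": 6000.0, "middle": 5200.0, "north": 5800.0}
    )
    pop_sigma: float = 0.30
    area_mean: Mapping[str, float] = field(
        default_factory=lambda: {"south": 5600.0, "middle": 6800.0, "north": 11000.0}
    )
    area_sigma: float = 0.25
    pop_growth: float = 1.002
    resources: Mapping[str, ResourceGen] = field(default_factory=_default_resources)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.years or list(self.years) != sorted(set(self.years)):
            raise ConfigError("years must be a nonempty strictly increasing tuple")
        if any(n <= 0 for n in self.region_sizes.values()):
            raise ConfigError("every region must contain at least one city")
        if self.pop_sigma < 0 or self.area_sigma < 0:
            raise ConfigError("size dispersion parameters must be >= 0")
        for name, rg in self.resources.items():
            if name not in INDICATOR_FIELDS:
                raise ConfigError(f"unknown resource field {name!r}")
            if rg.cv < 0:
                raise ConfigError(f"{name}: cv must be >= 0")
            if rg.base_rate < 0 or rg.growth <= 0:
                raise ConfigError(f"{name}: base_rate >= 0 and growth > 0 required")
            if any(m <= 0 for m in rg.multipliers.values()):
                raise ConfigError(f"{name}: multipliers must be > 0")

    @property
    def city_names(self) -> dict[str, list[str]]:
        return {
            reg: [f"{reg.capitalize()}-{i + 1:02d}" for i in range(n)]
            for reg, n in self.region_sizes.items()
        }


def _lognormal_mean(rng: np.random.Generator, mean: float, sigma: float, size: int) -> np.ndarray:
    """Log-normal draws with the requested arithmetic mean."""
    if sigma == 0:
        return np.full(size, mean)
    return rng.lognormal(np.log(mean) - sigma**2 / 2, sigma, size)


def generate_panel(config: PanelGenConfig | None = None) -> ResourcePanel:
    """Draw a balanced synthetic panel (deterministic given ``config.seed``)."""
    cfg = config or PanelGenConfig()
    names = cfg.city_names
    regions = sorted(names)
    cities = [(reg, c) for reg in regions for c in names[reg]]
    ncity = len(cities)

    rng_pop = np.random.default_rng([cfg.seed, _STREAMS["population"]])
    rng_area = np.random.default_rng([cfg.seed, _STREAMS["area"]])
    pop0 = np.concatenate(
        [_lognormal_mean(rng_pop, cfg.pop_mean.get(reg, 5000.0), cfg.pop_sigma, len(names[reg]))
         for reg in regions]
    )
    area = np.concatenate(
        [_lognormal_mean(rng_area, cfg.area_mean.get(reg, 8000.0), cfg.area_sigma, len(names[reg]))
         for reg in regions]
    )

    y0 = cfg.years[0]
    values: dict[str, np.ndarray] = {}  # field -> (ncity, nyears)
    nyears = len(cfg.years)
    # round sizes to the recorded precision *before* deriving resources, so a
    # zero-dispersion config yields exactly equal per-capita allocations
    area = np.round(area, 1)
    pop = np.round(
        np.array([pop0 * cfg.pop_growth ** (y - y0) for y in cfg.years]).T, 1
    )  # (ncity, nyears)

    for fname in INDICATOR_FIELDS:
        rg = cfg.resources.get(fname)
        if rg is None:
            values[fname] = np.zeros((ncity, nyears))
            continue
        rng = np.random.default_rng([cfg.seed, _STREAMS[fname]])
        city_eff = _lognormal_mean(rng, 1.0, rg.cv, ncity)
        year_noise = (
            _lognormal_mean(rng, 1.0, rg.cv / 4, ncity * nyears).reshape(ncity, nyears)
            if rg.cv > 0 else np.ones((ncity, nyears))
        )
        mult = np.array([rg.multipliers.get(reg, 1.0) for reg, _ in cities])
        growth = np.array([rg.growth ** (y - y0) for y in cfg.years])
        rate = rg.base_rate * mult[:, None] * city_eff[:, None] * year_noise * growth[None, :]
        v = rate * pop if rg.per_capita else rate
        if rg.clip is not None:
            v = np.clip(v, *rg.clip)
        if rg.integer:
            v = np.round(v)
        values[fname] = v

    records = []
    for i, (reg, city) in enumerate(cities):
        for k, year in enumerate(cfg.years):
            records.append(
                CityYearRecord(
                    city=city,
                    year=int(year),
                    region=reg,
                    population=float(pop[i, k]),
                    area=float(area[i]),
                    **{f: float(values[f][i, k]) for f in INDICATOR_FIELDS},
                )
            )
    return ResourcePanel(records, scheme_name="synthetic-3-zone")


@dataclass(frozen=True)
class FrontierGenConfig:
    """A known log-linear (Cobb–Douglas) production technology.

    elasticities: β per input field (Σβ = 1 gives constant returns to
    scale).  g: Hicks-neutral technology growth factor per year.  sigma_u:
    half-normal inefficiency scale (0 puts every city on the frontier).
    sigma_v: optional log-normal measurement noise on outputs (0 =
    deterministic frontier).  output_shares split the frontier aggregate
    across the output fields (they scale levels only; efficiency scores are
    unaffected).
    """

    input_fields: tuple[str, ...] = ("beds", "health_workers", "total_expenditure")
    elasticities: tuple[float, ...] = (0.4, 0.4, 0.2)
    output_fields: tuple[str, ...] = ("outpatient_volume", "general_income")
    output_shares: tuple[float, ...] = (1.0, 0.05)
    scale: float = 1.0
    g: float = 1.05
    sigma_u: float = 0.15
    sigma_v: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.input_fields) != len(self.elasticities):
            raise ConfigError("one elasticity per input field required")
        if len(self.output_fields) != len(self.output_shares):
            raise ConfigError("one share per output field required")
        if any(b < 0 for b in self.elasticities):
            raise ConfigError("elasticities must be >= 0")
        if self.g <= 0 or self.sigma_u < 0 or self.sigma_v < 0 or self.scale <= 0:
            raise ConfigError("g > 0, scale > 0 and sigmas >= 0 required")
        bad = [f for f in self.input_fields + self.output_fields if f not in INDICATOR_FIELDS]
        if bad:
            raise ConfigError(f"unknown indicator field(s): {bad}")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth behind a frontier panel: per city-year true radial
    efficiency exp(−u) and frontier aggregate output, plus the technology
    level per year."""

    frame: pd.DataFrame           # city, year, efficiency, frontier_output
    tech_levels: dict[int, float]


def generate_frontier_panel(
    config: FrontierGenConfig | None = None,
    base: PanelGenConfig | None = None,
) -> tuple[ResourcePanel, TruthRecord]:
    """Panel whose outputs follow a known technology with known inefficiency.

    Starts from :func:`generate_panel` (inputs, sizes) and replaces the
    configured output fields by ``share · A0 · g^(year−y0) · Π x^β · exp(−u)``
    (optionally times log-normal noise).  Returns the panel and the truth.
    """
    fcfg = config or FrontierGenConfig()
    bcfg = base or PanelGenConfig(seed=fcfg.seed)
    panel = generate_panel(bcfg)
    rng = np.random.default_rng([fcfg.seed, _FRONTIER_STREAM])
    y0 = panel.years[0]
    tech = {int(y): fcfg.scale * fcfg.g ** (y - y0) for y in panel.years}

    new_records = []
    truth_rows = []
    for city in panel.cities:
        for year in panel.years:
            rec = panel.record(city, year)
            x = np.array([getattr(rec, f) for f in fcfg.input_fields], dtype=float)
            if np.any(x <= 0):
                raise ConfigError(
                    f"frontier inputs must be positive; ({city}, {year}) has {x}"
                )
            F = tech[year] * float(np.prod(x ** np.asarray(fcfg.elasticities)))
            u = abs(rng.normal(0.0, fcfg.sigma_u)) if fcfg.sigma_u > 0 else 0.0
            eff = float(np.exp(-u))
            noise = float(np.exp(rng.normal(0.0, fcfg.sigma_v))) if fcfg.sigma_v > 0 else 1.0
            updates = {
                f: w * F * eff * noise
                for f, w in zip(fcfg.output_fields, fcfg.output_shares)
            }
            if "hospitalization_rate" in updates:
                updates["hospitalization_rate"] = min(updates["hospitalization_rate"], 100.0)
            new_records.append(replace(rec, **updates))
            truth_rows.append(
                {"city": city, "year": year, "efficiency": eff, "frontier_output": F}
            )
    truth = TruthRecord(
        frame=pd.DataFrame(truth_rows), tech_levels=tech
    )
    return ResourcePanel(new_records, scheme_name=panel.scheme_name), truth
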