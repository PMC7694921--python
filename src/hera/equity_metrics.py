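"""Equity statistics: Lorenz curves, weighted Gini, Theil decomposition, HRDI.

All measures compare how a health resource (beds, workers, finance, ...) is
spread over a *basis* — population or geographical area — across cities.

* The **Lorenz curve** plots cumulative resource share against cumulative
  basis share with cities sorted by resource-per-basis; the **Gini
  coefficient** is twice the area between the curve and the 45° equality
  diagonal, computed by the trapezoid rule
  ``G = 1 - sum_i (x_{i+1} - x_i) (y_i + y_{i+1})``.
* The **Theil index** ``T = sum_i P_i log(P_i / E_i)`` (P_i basis shares,
  E_i resource shares) decomposes additively over a region grouping into a
  within-region part ``T_intra = sum_g P_g T_g`` and a between-region part
  ``T_inter = sum_g P_g log(P_g / E_g)``; contribution rates are each part
  divided by the total.
* The **health resource density index** ``HRDI = HR / sqrt(A * P)`` is the
  resource amount over the geometric mean of area and population, balancing
  the demographic and geographic views of agglomeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_io import (
    INDICATOR_FIELDS,
    HeraError,
    PanelLookupError,
    PanelValidationError,
    ResourcePanel,
)

__all__ = [
    "DegenerateInputError",
    "TheilDivergenceError",
    "LorenzCurve",
    "GiniValue",
    "TheilDecomposition",
    "HrdiValue",
    "lorenz",
    "gini",
    "theil_total",
    "theil_decompose",
    "hrdi",
    "panel_gini",
    "panel_theil",
    "panel_hrdi",
    "equity_report",
    "plot_lorenz",
]


class DegenerateInputError(HeraError):
    """Total resource is zero; Lorenz/Gini are undefined."""


class TheilDivergenceError(HeraError):
    """A unit or group with positive basis share holds zero resource, so the
    Theil index diverges.  The caller must merge or drop such units
    explicitly; they are never dropped silently."""


@dataclass(frozen=True)
class LorenzCurve:
    """Ordered (cumulative basis share, cumulative resource share) points,
    starting at (0, 0) and ending at (1, 1)."""

    points: np.ndarray  # shape (n + 1, 2)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def gini(self) -> float:
        """Trapezoid-rule Gini of this curve."""
        x, y = self.x, self.y
        g = 1.0 - float(np.sum(np.diff(x) * (y[1:] + y[:-1])))
        if g < -1e-12:
            raise AssertionError(f"negative Gini {g}: curve not sorted correctly")
        return min(max(g, 0.0), 1.0 - 1e-300)


@dataclass(frozen=True)
class GiniValue:
    value: float
    resource: str = "resource"
    basis: str = "basis"

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class TheilDecomposition:
    """Total Theil index with its within/between-region decomposition.

    ``per_group`` maps each group label to (P_g, E_g, T_g): the group's basis
    share, resource share, and internal Theil index computed on within-group
    renormalized shares.  ``total = intra + inter`` holds by construction.
    """

    total: float
    intra: float
    inter: float
    per_group: Mapping[str, tuple[float, float, float]]
    contribution_intra: float
    contribution_inter: float
    log_base: str = "natural"


@dataclass(frozen=True)
class HrdiValue:
    value: float
    unit: str = ""

    def __float__(self) -> float:
        return self.value


def _as_positive_arrays(
    resource_values: Sequence[float], basis_values: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(resource_values, dtype=float)
    b = np.asarray(basis_values, dtype=float)
    if r.shape != b.shape or r.ndim != 1:
        raise ValueError("resource and basis values must be 1-D and equal length")
    if np.any(r < 0):
        raise PanelValidationError("resource values must be >= 0")
    if np.any(b <= 0):
        raise PanelValidationError("basis values must be > 0")
    if r.sum() <= 0:
        raise DegenerateInputError("total resource is zero; Lorenz curve undefined")
    return r, b


def lorenz(
    resource_values: Sequence[float],
    basis_values: Sequence[float],
    ids: Sequence[str] | None = None,
) -> LorenzCurve:
    """Lorenz curve of *resource* over *basis*.

    Units are sorted ascending by resource-per-basis ratio (ties broken by
    *ids* when given, else by input position, for determinism); cumulative
    shares are accumulated in that order and the origin is prepended.
    """
    r, b = _as_positive_arrays(resource_values, basis_values)
    ratio = r / b
    if ids is not None:
        order = np.lexsort((np.asarray(ids, dtype=object), ratio))
    else:
        order = np.argsort(ratio, kind="stable")
    x = np.concatenate(([0.0], np.cumsum(b[order]) / b.sum()))
    y = np.concatenate(([0.0], np.cumsum(r[order]) / r.sum()))
    x[-1] = 1.0
    y[-1] = 1.0
    return LorenzCurve(np.column_stack([x, y]))


def gini(
    resource_values: Sequence[float],
    basis_values: Sequence[float],
    ids: Sequence[str] | None = None,
    *,
    resource: str = "resource",
    basis: str = "basis",
) -> GiniValue:
    """Weighted Gini coefficient of resource concentration over a basis."""
    curve = lorenz(resource_values, basis_values, ids)
    return GiniValue(curve.gini(), resource=resource, basis=basis)


_LOG = {"natural": math.log, "base10": math.log10}


def theil_total(
    basis_shares: Sequence[float],
    resource_shares: Sequence[float],
    log_base: str = "natural",
) -> float:
    """Total Theil index ``T = sum_i P_i log(P_i / E_i)``.

    ``basis_shares`` (P_i) and ``resource_shares`` (E_i) must each sum to 1.
    Non-negative by Gibbs' inequality; zero iff P = E.
    """
    if log_base not in _LOG:
        raise ValueError(f"log_base must be one of {sorted(_LOG)}, got {log_base!r}")
    log = _LOG[log_base]
    P = np.asarray(basis_shares, dtype=float)
    E = np.asarray(resource_shares, dtype=float)
    if P.shape != E.shape or P.ndim != 1 or P.size == 0:
        raise ValueError("share vectors must be 1-D, equal length and nonempty")
    for name, v in (("basis", P), ("resource", E)):
        if abs(v.sum() - 1.0) > 1e-9:
            raise PanelValidationError(f"{name} shares must sum to 1, got {v.sum()!r}")
    if np.any(P <= 0):
        raise PanelValidationError("all basis shares must be > 0")
    if np.any((E == 0) & (P > 0)):
        raise TheilDivergenceError(
            "unit with positive basis share holds zero resource; Theil diverges "
            "(merge or drop the unit explicitly)"
        )
    return float(sum(p * log(p / e) for p, e in zip(P, E)))


def theil_decompose(
    basis_values: Sequence[float],
    resource_values: Sequence[float],
    groups: Sequence[str],
    log_base: str = "natural",
) -> TheilDecomposition:
    """Decompose the Theil index over a grouping of units.

    *basis_values* and *resource_values* are raw amounts (not shares); they
    are normalized internally.  For each group g, the internal index T_g is
    the Theil index of the group's units with shares renormalized to sum to 1
    within the group — the renormalization is what makes
    ``total = intra + inter`` an exact identity.
    """
    b = np.asarray(basis_values, dtype=float)
    r = np.asarray(resource_values, dtype=float)
    g = np.asarray(groups, dtype=object)
    if not (b.shape == r.shape == g.shape) or b.ndim != 1:
        raise ValueError("basis, resource and group arrays must be 1-D and equal length")
    P = b / b.sum()
    E_total = r.sum()
    if E_total <= 0:
        raise TheilDivergenceError("total resource is zero; Theil undefined")
    E = r / E_total

    total = theil_total(P, E, log_base)

    labels = sorted(set(g))
    log = _LOG[log_base]
    per_group: dict[str, tuple[float, float, float]] = {}
    intra = 0.0
    inter = 0.0
    for lab in labels:
        mask = g == lab
        P_g = float(P[mask].sum())
        E_g = float(E[mask].sum())
        if E_g == 0:
            raise TheilDivergenceError(f"group {lab!r} holds zero resource; Theil diverges")
        T_g = theil_total(P[mask] / P_g, E[mask] / E_g, log_base)
        per_group[lab] = (P_g, E_g, T_g)
        intra += P_g * T_g
        inter += P_g * log(P_g / E_g)

    if total > 0:
        c_intra, c_inter = intra / total, inter / total
    else:
        c_intra = c_inter = 0.0
    return TheilDecomposition(
        total=total,
        intra=intra,
        inter=inter,
        per_group=per_group,
        contribution_intra=c_intra,
        contribution_inter=c_inter,
        log_base=log_base,
    )


def hrdi(resource: float, area: float, population: float, unit: str = "") -> HrdiValue:
    """Health resource density index ``HR / sqrt(A * P)``.

    *area* in km², *population* in thousands of persons; the index is the
    resource amount per geometric mean of the two bases, so doubling both
    area and population halves nothing — it divides the index by 2 only
    jointly (by sqrt(2) each).
    """
    if area <= 0 or population <= 0:
        raise PanelValidationError("area and population must be > 0 for HRDI")
    if resource < 0:
        raise PanelValidationError("resource must be >= 0 for HRDI")
    return HrdiValue(resource / math.sqrt(area * population), unit=unit)


# ---------------------------------------------------------------------------
# Panel-level report tables
# ---------------------------------------------------------------------------

def _year_arrays(panel: ResourcePanel, resource: str, year: int):
    if resource not in INDICATOR_FIELDS:
        raise PanelLookupError(f"unknown resource field {resource!r}")
    recs = panel.year_slice(year)
    r = np.array([getattr(rec, resource) for rec in recs], dtype=float)
    pop = np.array([rec.population for rec in recs], dtype=float)
    area = np.array([rec.area for rec in recs], dtype=float)
    grp = np.array([rec.region for rec in recs], dtype=object)
    return recs, r, pop, area, grp


def panel_gini(panel: ResourcePanel, resource: str, basis: str, year: int) -> GiniValue:
    recs, r, pop, area, _ = _year_arrays(panel, resource, year)
    base = pop if basis == "population" else area
    if basis not in ("population", "area"):
        raise PanelLookupError(f"unknown basis {basis!r}")
    return gini(r, base, ids=[rec.city for rec in recs], resource=resource, basis=basis)


def panel_theil(
    panel: ResourcePanel, resource: str, basis: str, year: int, log_base: str = "natural"
) -> TheilDecomposition:
    _, r, pop, area, grp = _year_arrays(panel, resource, year)
    base = pop if basis == "population" else area
    if basis not in ("population", "area"):
        raise PanelLookupError(f"unknown basis {basis!r}")
    return theil_decompose(base, r, grp, log_base)


def panel_hrdi(panel: ResourcePanel, resource: str, year: int, by: str = "city") -> pd.Series:
    """HRDI per city, or per region with resources/area/population summed.

    The regional index is computed from group totals, *not* by averaging the
    member cities' indices — those two quantities differ whenever cities are
    heterogeneous.
    """
    recs, r, pop, area, grp = _year_arrays(panel, resource, year)
    if by == "city":
        vals = {rec.city: hrdi(ri, a, p).value for rec, ri, a, p in zip(recs, r, area, pop)}
    elif by == "region":
        vals = {}
        for lab in sorted(set(grp)):
            m = grp == lab
            vals[lab] = hrdi(float(r[m].sum()), float(area[m].sum()), float(pop[m].sum())).value
    else:
        raise PanelLookupError(f"unknown aggregation {by!r}; expected 'city' or 'region'")
    return pd.Series(vals, name=f"hrdi_{resource}")


def equity_report(
    panel: ResourcePanel,
    resources: Sequence[str],
    bases: Sequence[str] = ("population", "area"),
    log_base: str = "natural",
) -> dict[str, pd.DataFrame]:
    """All equity tables for a panel: per-year Gini, Theil decomposition with
    contribution-rate columns, per-region internal Theil, and HRDI by region
    and by city.  Returns a dict of tidy DataFrames keyed by table name."""
    gini_rows, theil_rows, tg_rows, hrdi_reg_rows, hrdi_city_rows = [], [], [], [], []
    for year in panel.years:
        for res in resources:
            for basis in bases:
                gini_rows.append(
                    {"year": year, "resource": res, "basis": basis,
                     "gini": panel_gini(panel, res, basis, year).value}
                )
                dec = panel_theil(panel, res, basis, year, log_base)
                theil_rows.append(
                    {"year": year, "resource": res, "basis": basis,
                     "theil_total": dec.total, "theil_intra": dec.intra,
                     "theil_inter": dec.inter,
                     "contribution_intra_pct": 100 * dec.contribution_intra,
                     "contribution_inter_pct": 100 * dec.contribution_inter}
                )
                for grp_label, (P_g, E_g, T_g) in dec.per_group.items():
                    tg_rows.append(
                        {"year": year, "resource": res, "basis": basis,
                         "region": grp_label, "P_g": P_g, "E_g": E_g, "T_g": T_g}
                    )
            for region, v in panel_hrdi(panel, res, year, by="region").items():
                hrdi_reg_rows.append(
                    {"year": year, "resource": res, "region": region, "hrdi": v}
                )
            for city, v in panel_hrdi(panel, res, year, by="city").items():
                hrdi_city_rows.append(
                    {"year": year, "resource": res, "city": city, "hrdi": v}
                )
    return {
        "gini": pd.DataFrame(gini_rows),
        "theil": pd.DataFrame(theil_rows),
        "theil_by_region": pd.DataFrame(tg_rows),
        "hrdi_by_region": pd.DataFrame(hrdi_reg_rows),
        "hrdi_by_city": pd.DataFrame(hrdi_city_rows),
    }


def plot_lorenz(
    panel: ResourcePanel,
    resources: Sequence[str],
    basis: str,
    year: int,
    path: str | None = None,
):
    """Lorenz curves for several resources in one year, with the 45° equality
    line.  Saves to *path* (PNG/SVG by extension) when given; returns the
    matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="absolute equality")
    for res in resources:
        recs, r, pop, area, _ = _year_arrays(panel, res, year)
        base = pop if basis == "population" else area
        curve = lorenz(r, base, ids=[rec.city for rec in recs])
        ax.plot(curve.x, curve.y, marker=".", label=res)
    ax.set_xlabel(f"cumulative {basis} share")
    ax.set_ylabel("cumulative resource share")
    ax.set_title(f"Lorenz curves, {year}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
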