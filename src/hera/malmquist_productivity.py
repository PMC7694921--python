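"""Adjacent-period Malmquist productivity indices and their decomposition.

Productivity change of a city between years t and t+1 is measured by ratios
of input-oriented distance functions D^a(x_b, y_b): the radial score of the
period-b observation against the period-a frontier.  Same-period scores lie
in (0, 1]; cross-period scores may exceed 1 (a point can dominate an older
frontier).  With CRS distances, the geometric-mean Malmquist construction
gives

    TEC  = D^{t+1}(t+1) / D^t(t)                       (catching up)
    TC   = sqrt[ (D^t(t+1)/D^{t+1}(t+1)) · (D^t(t)/D^{t+1}(t)) ]  (frontier shift)
    TFPC = TEC × TC

and the catching-up term splits against the VRS frontier as

    PTEC = D^{t+1}_VRS(t+1) / D^t_VRS(t),   SEC = TEC / PTEC.

Only same-period VRS distances are needed, so the cross-period VRS
infeasibility pathology never arises.  Values above 1 indicate improvement.
Summaries report geometric means (the MPI convention) by year-pair and by
city, with >1 / =1 / <1 frequency counts per component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dea_efficiency import DeaModelSpec, build_matrices, solve_envelopment
from .panel_io import PanelLookupError, ResourcePanel

__all__ = [
    "MalmquistRecord",
    "MalmquistSummary",
    "cross_distance",
    "malmquist_pair",
    "malmquist_all",
    "summarize",
    "records_frame",
    "summary_frame",
]

_EQ_TOL = 1e-9


@dataclass(frozen=True)
class MalmquistRecord:
    """One city's productivity decomposition over one adjacent year pair.
    tfpc = tec·tc and tec = ptec·sec hold by construction."""

    dmu: str
    period_pair: tuple[int, int]
    tec: float
    tc: float
    ptec: float
    sec: float
    tfpc: float


@dataclass(frozen=True)
class MalmquistSummary:
    by: str                      # 'year' or 'city'
    key: str
    tec: float
    tc: float
    ptec: float
    sec: float
    tfpc: float
    freq_gt1: dict[str, int]
    freq_eq1: dict[str, int]
    freq_lt1: dict[str, int]


def cross_distance(
    x0: np.ndarray,
    y0: np.ndarray,
    frontier_inputs: np.ndarray,
    frontier_outputs: np.ndarray,
    rts: str = "CRS",
) -> float:
    """Input-oriented distance of point (x0, y0) to a given frontier.

    Same-period evaluation (point belongs to the frontier set) returns
    θ ∈ (0, 1]; cross-period evaluation may return θ > 1.
    """
    theta, _ = solve_envelopment(
        0, frontier_inputs, frontier_outputs, rts,
        point=(np.asarray(x0, float), np.asarray(y0, float)),
    )
    return theta


def malmquist_pair(
    panel: ResourcePanel, t: int, spec: DeaModelSpec | None = None
) -> list[MalmquistRecord]:
    """Malmquist decomposition for every city over the pair (t, t+1)."""
    spec = spec or DeaModelSpec()
    if t not in panel.years or t + 1 not in panel.years:
        raise PanelLookupError(f"panel lacks the adjacent years ({t}, {t + 1})")
    cities, Xt, Yt = build_matrices(panel, t, spec)
    _, Xs, Ys = build_matrices(panel, t + 1, spec)
    # one common rescaling across both periods keeps cross-period distances
    # coherent (scores are units-invariant under a shared column scale)
    sx = np.vstack([Xt, Xs]).mean(axis=0)
    sy = np.vstack([Yt, Ys]).mean(axis=0)
    sy = np.where(sy > 0, sy, 1.0)
    Xt, Xs = Xt / sx, Xs / sx
    Yt, Ys = Yt / sy, Ys / sy

    out = []
    for j, city in enumerate(cities):
        d_t_t = solve_envelopment(j, Xt, Yt, "CRS")[0]
        d_s_s = solve_envelopment(j, Xs, Ys, "CRS")[0]
        d_t_s = cross_distance(Xs[j], Ys[j], Xt, Yt, "CRS")
        d_s_t = cross_distance(Xt[j], Yt[j], Xs, Ys, "CRS")
        v_t_t = solve_envelopment(j, Xt, Yt, "VRS")[0]
        v_s_s = solve_envelopment(j, Xs, Ys, "VRS")[0]
        tec = d_s_s / d_t_t
        tc = math.sqrt((d_t_s / d_s_s) * (d_t_t / d_s_t))
        ptec = v_s_s / v_t_t
        sec = tec / ptec
        out.append(
            MalmquistRecord(
                dmu=city, period_pair=(t, t + 1),
                tec=tec, tc=tc, ptec=ptec, sec=sec, tfpc=tec * tc,
            )
        )
    return out


def malmquist_all(
    panel: ResourcePanel, spec: DeaModelSpec | None = None
) -> list[MalmquistRecord]:
    """Malmquist records for every adjacent year pair in the panel."""
    recs: list[MalmquistRecord] = []
    for t in panel.years[:-1]:
        if t + 1 in panel.years:
            recs.extend(malmquist_pair(panel, t, spec))
    return recs


_COMPONENTS = ("tec", "tc", "ptec", "sec", "tfpc")


def _geomean(vals: Sequence[float]) -> float:
    return float(np.exp(np.mean(np.log(vals))))


def summarize(
    records: Sequence[MalmquistRecord], by: str = "year", geometric: bool = True
) -> list[MalmquistSummary]:
    """Geometric-mean summaries with >1 / =1 / <1 frequency counts.

    ``by='year'`` groups over year pairs (counting cities); ``by='city'``
    groups over cities (counting period pairs).  ``geometric=False`` switches
    to arithmetic means for sensitivity checks.
    """
    if not records:
        raise ValueError("no Malmquist records to summarize")
    if by == "year":
        keyfn = lambda r: f"{r.period_pair[0]}-{r.period_pair[1]}"
    elif by == "city":
        keyfn = lambda r: r.dmu
    else:
        raise ValueError(f"by must be 'year' or 'city', got {by!r}")
    mean = _geomean if geometric else (lambda v: float(np.mean(v)))
    groups: dict[str, list[MalmquistRecord]] = {}
    for r in records:
        groups.setdefault(keyfn(r), []).append(r)
    out = []
    for key in sorted(groups):
        rs = groups[key]
        means = {c: mean([getattr(r, c) for r in rs]) for c in _COMPONENTS}
        gt = {c: sum(1 for r in rs if getattr(r, c) > 1 + _EQ_TOL) for c in _COMPONENTS}
        eq = {c: sum(1 for r in rs if abs(getattr(r, c) - 1) <= _EQ_TOL) for c in _COMPONENTS}
        lt = {c: sum(1 for r in rs if getattr(r, c) < 1 - _EQ_TOL) for c in _COMPONENTS}
        out.append(
            MalmquistSummary(by=by, key=key, freq_gt1=gt, freq_eq1=eq, freq_lt1=lt, **means)
        )
    return out


def records_frame(records: Sequence[MalmquistRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "city": [r.dmu for r in records],
            "pair": [f"{r.period_pair[0]}-{r.period_pair[1]}" for r in records],
            "TEC": [r.tec for r in records],
            "TC": [r.tc for r in records],
            "PTEC": [r.ptec for r in records],
            "SEC": [r.sec for r in records],
            "TFPC": [r.tfpc for r in records],
        }
    )


def summary_frame(summaries: Sequence[MalmquistSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {s.by: s.key, "TEC": s.tec, "TC": s.tc, "PTEC": s.ptec,
               "SEC": s.sec, "TFPC": s.tfpc}
        for c in _COMPONENTS:
            row[f"n_gt1_{c}"] = s.freq_gt1[c]
            row[f"n_eq1_{c}"] = s.freq_eq1[c]
            row[f"n_lt1_{c}"] = s.freq_lt1[c]
        rows.append(row)
    return pd.DataFrame(rows)
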