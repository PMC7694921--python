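"""Input-oriented DEA: CCR/BCC envelopment programs, slacks, adjustment targets.

Each city is a decision-making unit (DMU) evaluated against the frontier
spanned by all cities observed in the *same year*.  The radial envelopment
program shrinks the DMU's inputs by a common factor θ until they meet the
free-disposal convex hull of the observed data:

    min θ   s.t.  Σ_j λ_j x_j ≤ θ x_0,   Σ_j λ_j y_j ≥ y_0,   λ ≥ 0,
    (BCC/VRS adds Σ_j λ_j = 1)

The CCR program (constant returns to scale) gives overall technical
efficiency TE; the BCC program (variable returns) gives pure technical
efficiency PTE; scale efficiency is SE = TE / PTE, so TE = PTE × SE.

A second phase fixes θ and maximizes the sum of remaining input excesses and
output shortfalls (slacks), which avoids the non-Archimedean ε of the
single-stage formulation.  Adjustment targets follow the input-oriented
projection: each input must change by (θ_VRS − 1)·x − s⁻ ≤ 0 and each output
by +s⁺ ≥ 0; a VRS-efficient DMU with zero slacks needs no adjustment.

Inputs default to the five resource indicators (institutions, beds and
health workers per 1000 persons; government subsidies and total expenditures
in billions) and outputs to outpatient volume, hospitalization rate and
general income.  Columns are rescaled to unit mean before solving purely for
LP conditioning — radial scores are units-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .panel_io import HeraError, ResourcePanel

__all__ = [
    "DeaSolverError",
    "DeaModelSpec",
    "DmuScore",
    "AdjustmentRow",
    "build_matrices",
    "solve_envelopment",
    "max_slacks",
    "efficiency_table",
    "adjustment_table",
    "scores_frame",
    "adjustments_frame",
    "EFFICIENT_TOL",
]

#: θ within this of 1 is classified efficient for reporting (raw θ retained).
EFFICIENT_TOL = 1e-6

_SOLVER_TOL = 1e-7


class DeaSolverError(HeraError):
    """The envelopment LP failed to solve (indicates invalid data)."""


@dataclass(frozen=True)
class DeaModelSpec:
    """Input/output variable selection for the DEA runs.

    ``per_capita_fields`` are expressed per 1000 persons when the matrices
    are built (counts divided by population-in-thousands); all other fields
    enter at their recorded values.
    """

    input_fields: tuple[str, ...] = (
        "institutions", "beds", "health_workers", "gov_subsidy", "total_expenditure",
    )
    output_fields: tuple[str, ...] = (
        "outpatient_volume", "hospitalization_rate", "general_income",
    )
    orientation: str = "input"
    per_capita_fields: tuple[str, ...] = ("institutions", "beds", "health_workers")

    def __post_init__(self) -> None:
        if not self.input_fields or not self.output_fields:
            raise ValueError("need at least one input and one output field")
        if self.orientation != "input":
            raise ValueError("only input orientation is supported")


@dataclass(frozen=True)
class DmuScore:
    """Radial efficiencies and slacks of one DMU for one year."""

    dmu: str
    theta_crs: float   # TE
    theta_vrs: float   # PTE
    scale_eff: float   # SE = TE / PTE
    lambdas: np.ndarray        # VRS intensity weights over peer DMUs
    input_slacks: np.ndarray   # VRS phase-2, original units
    output_slacks: np.ndarray
    peers: tuple[str, ...]

    @property
    def efficient_vrs(self) -> bool:
        return self.theta_vrs >= 1.0 - EFFICIENT_TOL


@dataclass(frozen=True)
class AdjustmentRow:
    """Signed input/output changes (target − observed) needed for a DMU to
    reach the VRS frontier; inputs ≤ 0, outputs ≥ 0."""

    dmu: str
    input_variations: np.ndarray
    output_variations: np.ndarray


def build_matrices(
    panel: ResourcePanel, year: int, spec: DeaModelSpec
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Extract the (cities, inputs n×m, outputs n×s) arrays for one year."""
    recs = panel.year_slice(year)
    cities = [r.city for r in recs]

    def value(rec, f: str) -> float:
        v = float(getattr(rec, f))
        if f in spec.per_capita_fields:
            v /= rec.population
        return v

    X = np.array([[value(r, f) for f in spec.input_fields] for r in recs])
    Y = np.array([[value(r, f) for f in spec.output_fields] for r in recs])
    if np.any(X <= 0):
        raise DeaSolverError(f"year {year}: all DEA inputs must be strictly positive")
    if np.any(Y.max(axis=1) <= 0):
        raise DeaSolverError(f"year {year}: every DMU needs at least one positive output")
    return cities, X, Y


def _scale_columns(X: np.ndarray, Y: np.ndarray):
    sx = X.mean(axis=0)
    sy = Y.mean(axis=0)
    sy = np.where(sy > 0, sy, 1.0)
    return X / sx, Y / sy, sx, sy


def solve_envelopment(
    dmu_index: int,
    inputs: np.ndarray,
    outputs: np.ndarray,
    rts: str = "CRS",
    *,
    point: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, np.ndarray]:
    """Radial input-oriented envelopment LP for one DMU.

    The frontier is spanned by the rows of *inputs*/*outputs*.  By default
    the evaluated point is row *dmu_index*; *point* substitutes an external
    (x0, y0) — used for cross-period distance functions, where θ may
    exceed 1.  Returns (θ, λ).
    """
    n, m = inputs.shape
    s = outputs.shape[1]
    if point is None:
        x0, y0 = inputs[dmu_index], outputs[dmu_index]
    else:
        x0, y0 = point
    # variables: [theta, lambda_1..lambda_n]
    c = np.zeros(1 + n)
    c[0] = 1.0
    A_ub = np.zeros((m + s, 1 + n))
    b_ub = np.zeros(m + s)
    A_ub[:m, 0] = -x0
    A_ub[:m, 1:] = inputs.T          # Σ λ x_j − θ x0 ≤ 0
    A_ub[m:, 1:] = -outputs.T        # −Σ λ y_j ≤ −y0
    b_ub[m:] = -y0
    A_eq = b_eq = None
    if rts == "VRS":
        A_eq = np.zeros((1, 1 + n))
        A_eq[0, 1:] = 1.0
        b_eq = np.array([1.0])
    elif rts != "CRS":
        raise ValueError(f"rts must be 'CRS' or 'VRS', got {rts!r}")
    bounds = [(None, None)] + [(0, None)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if not res.success:
        raise DeaSolverError(
            f"envelopment LP failed for DMU index {dmu_index} ({rts}): {res.message}"
        )
    theta = float(res.x[0])
    if theta <= 0:
        raise DeaSolverError(f"non-positive radial score {theta} for DMU {dmu_index}")
    return theta, res.x[1:].copy()


def max_slacks(
    dmu_index: int,
    theta: float,
    inputs: np.ndarray,
    outputs: np.ndarray,
    rts: str = "CRS",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phase-2 LP: with θ fixed, maximize total input excess + output
    shortfall.  Returns (input_slacks, output_slacks, λ); the projected point
    (θ x − s⁻, y + s⁺) lies on the efficient frontier."""
    n, m = inputs.shape
    s = outputs.shape[1]
    x0, y0 = inputs[dmu_index], outputs[dmu_index]
    # variables: [lambda_1..n, s_minus_1..m, s_plus_1..s]
    nv = n + m + s
    c = np.zeros(nv)
    c[n:] = -1.0  # maximize slack sum
    A_eq = np.zeros((m + s, nv))
    b_eq = np.zeros(m + s)
    A_eq[:m, :n] = inputs.T
    A_eq[:m, n:n + m] = np.eye(m)            # Σ λ x + s⁻ = θ x0
    b_eq[:m] = theta * x0
    A_eq[m:, :n] = outputs.T
    A_eq[m:, n + m:] = -np.eye(s)            # Σ λ y − s⁺ = y0
    b_eq[m:] = y0
    if rts == "VRS":
        row = np.zeros((1, nv))
        row[0, :n] = 1.0
        A_eq = np.vstack([A_eq, row])
        b_eq = np.append(b_eq, 1.0)
    elif rts != "CRS":
        raise ValueError(f"rts must be 'CRS' or 'VRS', got {rts!r}")
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=[(0, None)] * nv, method="highs")
    if not res.success:
        raise DeaSolverError(
            f"slack LP failed for DMU index {dmu_index} ({rts}): {res.message}"
        )
    lam = res.x[:n].copy()
    s_in = np.maximum(res.x[n:n + m], 0.0)
    s_out = np.maximum(res.x[n + m:], 0.0)
    return s_in, s_out, lam


def efficiency_table(
    panel: ResourcePanel, year: int, spec: DeaModelSpec | None = None
) -> list[DmuScore]:
    """TE (CRS), PTE (VRS), SE = TE/PTE and VRS slacks for every city in one
    year, each evaluated against that year's own frontier."""
    spec = spec or DeaModelSpec()
    cities, X, Y = build_matrices(panel, year, spec)
    Xs, Ys, sx, sy = _scale_columns(X, Y)
    scores = []
    for j, city in enumerate(cities):
        t_crs, _ = solve_envelopment(j, Xs, Ys, "CRS")
        t_vrs, _ = solve_envelopment(j, Xs, Ys, "VRS")
        t_crs = min(t_crs, 1.0)
        t_vrs = min(t_vrs, 1.0)
        s_in, s_out, lam = max_slacks(j, t_vrs, Xs, Ys, "VRS")
        # back to original units; clamp solver dust to exact zero
        s_in = np.where(s_in > _SOLVER_TOL, s_in * sx, 0.0)
        s_out = np.where(s_out > _SOLVER_TOL, s_out * sy, 0.0)
        lam = np.where(lam > _SOLVER_TOL, lam, 0.0)
        peers = tuple(cities[k] for k in np.nonzero(lam)[0])
        scores.append(
            DmuScore(
                dmu=city,
                theta_crs=t_crs,
                theta_vrs=t_vrs,
                scale_eff=t_crs / t_vrs,
                lambdas=lam,
                input_slacks=s_in,
                output_slacks=s_out,
                peers=peers,
            )
        )
    return scores


def adjustment_table(
    scores: Sequence[DmuScore], inputs: np.ndarray, outputs: np.ndarray
) -> list[AdjustmentRow]:
    """Input/output variations needed to reach the VRS frontier.

    *inputs*/*outputs* are the original-unit matrices (row order matching
    *scores*).  input variation = (θ_VRS − 1)·x − s⁻; output variation = s⁺.
    """
    rows = []
    for j, sc in enumerate(scores):
        dv_in = (sc.theta_vrs - 1.0) * inputs[j] - sc.input_slacks
        dv_out = sc.output_slacks.copy()
        if sc.efficient_vrs:
            # radial part is solver dust for efficient DMUs; keep true zeros
            dv_in = -sc.input_slacks
        dv_in = np.where(np.abs(dv_in) > _SOLVER_TOL * np.maximum(np.abs(inputs[j]), 1.0),
                         dv_in, 0.0)
        rows.append(AdjustmentRow(sc.dmu, np.minimum(dv_in, 0.0), dv_out))
    return rows


def scores_frame(scores: Sequence[DmuScore], summary: bool = True) -> pd.DataFrame:
    """Tidy score table with an optional mean/max/min summary block."""
    df = pd.DataFrame(
        {
            "city": [s.dmu for s in scores],
            "TE": [s.theta_crs for s in scores],
            "PTE": [s.theta_vrs for s in scores],
            "SE": [s.scale_eff for s in scores],
            "peers": [";".join(s.peers) for s in scores],
        }
    )
    if summary:
        num = df[["TE", "PTE", "SE"]]
        block = pd.DataFrame(
            {
                "city": ["Mean", "Maxi", "Mini"],
                "TE": [num.TE.mean(), num.TE.max(), num.TE.min()],
                "PTE": [num.PTE.mean(), num.PTE.max(), num.PTE.min()],
                "SE": [num.SE.mean(), num.SE.max(), num.SE.min()],
                "peers": ["", "", ""],
            }
        )
        df = pd.concat([df, block], ignore_index=True)
    return df


def adjustments_frame(
    rows: Sequence[AdjustmentRow], spec: DeaModelSpec
) -> pd.DataFrame:
    data = {"city": [r.dmu for r in rows]}
    for i, f in enumerate(spec.input_fields):
        data[f"d_{f}"] = [r.input_variations[i] for r in rows]
    for i, f in enumerate(spec.output_fields):
        data[f"d_{f}"] = [r.output_variations[i] for r in rows]
    return pd.DataFrame(data)
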