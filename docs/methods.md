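# Methods

This note records the statistical and numerical choices behind `hera`: what
each measure assumes, the defaults and why, what the synthetic generator
does and does not emulate, and known limitations.

## Panel model

The unit of analysis is a city observed in a calendar year.  Population is
stored in thousands of persons so `resource / population` is directly a
per-1000-person density; area is in km².  The panel must be **balanced**
(every city present in every year): the yearly DEA frontier and the
adjacent-year Malmquist comparison both assume a constant set of
decision-making units, and silently dropping a city would move the frontier
for every other city.  Unbalancedness is therefore a hard read-time error
that lists the missing (city, year) pairs rather than a warning.

A region scheme partitions cities into groups (default: the 5/3/5
south–middle–north zoning of Jiangsu's 13 prefecture-level cities).  Groups
must be disjoint and cover the panel.

Province-level densities are totals over totals, never means of city
densities — the two differ whenever city sizes differ, and only the former
matches published provincial density tables.

## Equity measures

**Lorenz/Gini.** Cities are sorted ascending by resource-per-basis ratio
(ties broken by city identifier; the Gini value is provably tie-order
invariant), cumulative shares accumulated in that order, and the Gini
computed by the trapezoid rule on the resulting curve.  This is the standard
weighted formulation in which the curve lies on or below the diagonal and
G ∈ [0, 1); it agrees with the O(n²) weighted mean-absolute-difference form
Σᵢⱼ wᵢwⱼ|rᵢ−rⱼ|/(2μ) to machine precision (asserted in tests at 1e−12).
Basis values must be strictly positive and total resource nonzero; a
zero-resource vector is a degenerate-input error, not a zero.

**Theil.** `T = Σ Pᵢ log(Pᵢ/Eᵢ)` with P the basis (population or area)
shares and E the resource shares.  The grouped decomposition renormalizes
shares *within* each group before computing the group index T_g; that
renormalization is exactly what makes `T = Σ P_g T_g + Σ P_g log(P_g/E_g)`
an identity (checked to 1e−10 on arbitrary random groupings).  Contribution
rates are each part over the total.  The logarithm base is a free
convention; natural log is the default and base 10 is available — all
decomposition identities and zero/positivity properties are base-invariant,
and only the absolute magnitude of T changes.  A unit (or group) with
positive basis share and zero resource makes T diverge; this raises an
error so the caller merges or drops units deliberately.

**HRDI.** `HR/√(A·P)`.  Regional values are computed from group *totals*;
averaging member-city indices is a different (and wrong) quantity, and a
regression test pins the distinction.

## DEA

Input-oriented envelopment form, solved per year with `scipy.optimize.linprog`
(HiGHS): minimize θ subject to Σλⱼxⱼ ≤ θx₀, Σλⱼyⱼ ≥ y₀, λ ≥ 0, plus
Σλ = 1 under variable returns.  Input orientation matches the policy
semantics of adjustment tables that *reduce* inputs and *raise* outputs.
Choices that matter:

* **Two-phase slacks.** Radial θ first, then a second LP maximizing the
  slack sum with θ fixed.  This avoids the non-Archimedean ε of the
  single-stage formulation and is the numerically robust standard.
* **Conditioning.** All columns are rescaled to unit mean before solving;
  radial scores are units-invariant (tested to 1e−9 under column rescaling
  by 10³), so results are unaffected while the LP basis is well-scaled.
  Slacks are mapped back to original units.
* **Tolerances.** Solver feasibility tolerance 1e−7; λ, slack and variation
  entries below that (relative) threshold are clamped to exact zero so that
  efficient cities produce genuinely all-zero adjustment rows.  θ ≥ 1−1e−6
  classifies a DMU as efficient for reporting; raw θ is retained.
* **Percentage outputs.** The hospitalization rate enters as an ordinary
  output with no bounded-variable transformation, consistent with
  yearbook-style DEA practice.
* **Degeneracy.** Alternative optimal λ (peer sets) are not disambiguated;
  the solver's vertex solution is reported.  Radial scores themselves are
  unique.

Cross-checks: CRS scores equal the closed-form best-ratio oracle on
1-input/1-output data (1e−9, 500 random instances); TE ≤ PTE always;
duplicating a DMU changes nothing; worsening an input never raises θ;
projected points re-evaluate as efficient.

## Malmquist productivity

Adjacent year pairs only.  CRS distances drive TFPC, TEC and TC, with the
geometric-mean (two-frontier) form of TC; PTEC uses same-period VRS
distances and SEC = TEC/PTEC.  Because VRS is never evaluated cross-period,
the well-known cross-period VRS infeasibility cannot occur.  Both
period-pair matrices share one column scaling so cross-period distances are
coherent.  Identities TFPC = TEC·TC and TEC = PTEC·SEC are exact by
construction; tests guard them against refactoring.  Summaries use
geometric means (arithmetic available behind a flag) and report >1 / =1 / <1
frequency counts per component with an equality tolerance of 1e−9.

## Synthetic generator

`generate_panel` draws the study conditions the analyses are validated
under: 13 cities in three zones (5/3/5) over 2014–2018; log-normal
populations (regional means 6.0/5.2/5.8 million, σ_log 0.30) and areas
(5.6/6.8/11.0 thousand km², σ_log 0.25) at provincial magnitudes; per-capita
resource rates with regional multipliers, persistent log-normal city effects
(σ = cv), small year noise (cv/4) and smooth multiplicative growth.  Default
rates start at yearbook-scale magnitudes (e.g. 4.93 beds and 7.41 health
workers per 1000 persons, growing ≈5.5 %/year; subsidies growing ≈16 %/year)
with beds/workers/finance concentrated in the south (multipliers 1.35–1.9
south vs 0.5–0.72 north) and institutions nearly per-capita-even.  Under
these defaults the between-region share of the beds Theil index exceeds 50 %
(measured ≈ 92–94 %) and the population-basis Gini of institutions stays
below 0.15 in expectation (measured ≈ 0.11) — the qualitative regime of a
developed coastal province.  Each indicator draws from its own fixed
sub-stream of the seeded generator, so adding an indicator never perturbs
the others and equal-multiplier/zero-dispersion configs produce exactly zero
inequality.

`generate_frontier_panel` overwrites chosen output fields with
`share · A₀ · g^(year−y₀) · Πxᵢ^βᵢ · exp(−u)`: a Cobb–Douglas frontier
(default elasticities 0.4/0.4/0.2 on beds, workers and expenditure — constant
returns), Hicks-neutral growth g (default 1.05/year), half-normal
inefficiency u (default σ_u = 0.15) and optional log-normal noise.  The
returned truth record holds every drawn efficiency and the technology level
per year.

What the generator does **not** emulate: spatial autocorrelation, migration
between cities, serially correlated inefficiency, measurement error in the
yearbook indicators, or any calibration to real per-city marginals (which
are not public).  Passing recovery tests therefore demonstrate estimator
correctness under a clean data-generating process, not robustness to real
survey artifacts.

## Problem sizes used in validation

Test and acceptance runs use the native study size (13 DMUs, 5 years)
throughout; oracle suites use 150–500 random instances of n ≤ 20 (equity)
or n ≤ 6 (DEA), and recovery experiments average 10–20 seeds.  At n = 13
DEA scores are noticeably upward-biased estimates of true efficiency
(mean bias ≈ +0.05 at σ_u = 0.15); the suite asserts the direction of this
bias rather than pretending it away, and rank recovery (Spearman ≈ 0.86–0.89
between drawn and estimated efficiencies) is the meaningful finite-sample
guarantee.  No bias correction (e.g. bootstrap) is applied to efficiency or
productivity scores.

## Known limitations

* Point estimates only: no standard errors or bootstrap intervals for G, T,
  DEA or Malmquist results.
* Input-oriented radial models only; no output orientation, SBM/directional
  distance, or sequential/global-frontier Malmquist variants.
* Peer sets under degenerate optima may differ across LP solver versions;
  scores do not.
* The published provincial summary tables bundled for identity
  recomposition contain a handful of cells inconsistent with their own rows
  at the printed 3-dp precision (one rounding ulp); those cells are listed
  in `hera.jiangsu_reference` and excluded from recomposition checks.
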