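# Methods

## Model

The package implements a two-strategy symmetric game played in a large,
well-mixed population. Strategy C (cooperate) is regular sunscreen use;
strategy D (defect) is non-use. The pairwise payoff matrix, with effective
cost `C' = C − s`,

|        | C                  | D                    |
|--------|--------------------|----------------------|
| **C**  | (B−C', B−C')       | (B−C'−E, 0)          |
| **D**  | (0, B−C'−E)        | (−E, −E)             |

encodes: a cooperator always pays `C'` and receives `B`; each defector in a
pairing imposes the externality `E` (expected publicly financed treatment
cost) on the other player; a defector pays nothing privately. At population
share `x` of cooperators the expected payoffs are `π_C = B − C' − E(1−x)`
and `π_D = −E(1−x)`, and the replicator equation `dx/dt = x(π_C − π̄)`
reduces to `dx/dt = x(1−x)(B − C + s)`.

Model assumptions worth keeping in view:

- **Homogeneous population, infinite size.** No heterogeneity in risk,
  income or preferences; no finite-population drift (no Moran or
  Wright–Fisher dynamics).
- **Externality symmetry.** Shared financing hits users and non-users
  alike, so `E` cancels from the dynamics. Consequently the baseline model
  has a dominance structure: no interior equilibria, no tipping points.
- **Expected-value payoffs.** No risk aversion, no discounting; the
  lifetime cost and benefit are compared as undiscounted totals.
- **Abstract time scale.** The replicator time unit is not calibrated to
  calendar time; only the sign and relative magnitude of the payoff gap
  matter. The payoff-to-fitness proportionality constant is 1.

Frequency-dependent extensions enter through a payoff-difference function
`g(x)` replacing the constant `B − C + s`; the package provides the solver
machinery (integration, root-finding, stability) but deliberately fixes no
functional form for social-norm effects, since any particular form would be
a modelling commitment of its own.

## Calibration

The economic pipeline maps eleven scenario parameters to the game payoffs.
Defaults (the bundled `australia.yaml`) are the reference Australian
scenario:

| parameter | default | units | meaning |
|---|---|---|---|
| `p` | 0.0674 | — | lifetime melanoma risk (national incidence figure) |
| `rr` | 0.50 | — | relative risk under daily sunscreen use (trial follow-up) |
| `k_med` | 11,788 | AUD | direct medical cost per case |
| `v_per_qaly` | 75,000 | AUD | monetary value per QALY (assumption; sweepable) |
| `dqaly` | 1.0 | QALY | loss per case (unweighted by stage) |
| `price` | 10.99 | AUD | retail price per bottle |
| `volume_ml` | 110 | mL | bottle volume |
| `ml_per_day` | 20 | mL | application for exposed skin |
| `days_per_year` | 90 | days | sunny days per summer |
| `years` | 60 | — | horizon (roughly ages 15–75) |
| `theta` | 0.20 | — | private share of the per-case loss |

Derived quantities: `C = (price/volume) · mL/day · days · years`
(10,790.18 AUD at defaults), `K = k_med + V·ΔQALY` (86,788 AUD),
`B+E = p(1−RR)K`, `B = θ(B+E)`, `E = (1−θ)(B+E)` computed as `total − B` so
the split conserves the total exactly in floating point.

**Rounding convention.** All computation runs at full precision. Display
tables round half-up to integer AUD, and the minimum subsidy is computed on
the rounded integers, `s* = C_r − B_r`, floored at 0. This single
convention reproduces the published Australian table except for two
average-row cells (computed 2,925/2,340 vs printed 2,924/2,339) that are
inconsistent with the table's own formulas under any uniform rounding rule;
the tests carry a ±1 AUD tolerance on exactly those cells and the package
does not reverse-engineer a per-row rule. The average-risk row uses
p = 0.0674 (the published incidence figure), which is what the printed row
values require even though the row label shows 0.067.

**Regimes.** Private incentive (`B` vs `C`) and social efficiency (`B+E`
vs `C`) classify each scenario into `private_adoption`,
`efficient_non_adoption`, `inefficient_non_adoption`, or
`neutral_boundary` when either comparison is an exact tie — ties are
surfaced, never silently assigned. Closed-form thresholds:
`p_social = C/((1−RR)K)` ≈ 0.2487 at defaults; `p_private = C/(θ(1−RR)K)`
≈ 1.243, above 1 and therefore flagged unreachable rather than clamped.

## Numerics

- **Closed form.** The constant-gap dynamics are logistic;
  `x(t) = expit(logit(x0) + k t)` is exact and saturates cleanly to the
  correct boundary for any `kt` (no overflow at the calibrated `k ≈ 1e4`).
- **Integrator.** `scipy.integrate.solve_ivp` (RK45, rtol 1e-9,
  atol 1e-12). Time is rescaled internally by `M = max|g|` over a 257-point
  probe grid so that currency-scale payoff gaps integrate with the same
  effective step control as O(1) gaps; states are clipped to [0, 1] after
  solving to absorb drift at the absorbing boundaries. Solver failure
  raises, never returns silently.
- **Equilibria.** The boundaries 0 and 1 are always rest points. Interior
  rest points are sign-change roots of `g`, bracketed on a 1,025-point
  uniform grid and refined by Brent bisection to 1e-10. Stability comes
  from the flow direction on either side (1e-6 offset); `g` vanishing
  everywhere on the grid (≤1e-12) is reported as a neutral continuum
  rather than forcing labels. Reports with interior equilibria carry the
  regime label `frequency_dependent`.
- **Subsidy semantics.** The selection coefficient is computed as
  `B − (C − s)` so a subsidy is bit-for-bit identical to the equivalent
  cost reduction. At `s = s*` exactly the dynamics are neutral; flipping
  the regime requires strictly exceeding `s*` (the boundary is not
  adopting).
- **Sweeps.** One-dimensional sweeps recompute the full calibration per
  grid value; each sign change of `B − C` or `B+E − C` between adjacent
  grid points is refined by bisection to 1e-8 of the grid span. Where a
  closed form exists (risk thresholds, `θ* = C/(B+E)`), bisection and
  closed form agree to 1e-6 relative — this is tested. Note that at
  p = 0.25 the total benefit (10,848.5 AUD) exceeds C (10,790.18 AUD), so a
  θ-sweep *does* cross the private boundary at θ* ≈ 0.9946.

## Burden estimate

The cohort burden is the plain product
`population × share_age × share_sex × share_risk × cost_per_case`,
assuming one treated case per high-risk cohort member — an upper-bound
simplification, not an incidence model. At the bundled cohort
(27.6M × 0.23 × 0.496 × 0.60 × 8,679 AUD) the product is
16,396,061,299.2 AUD. The scenario may carry an externally reported
reference total (`headline_total_aud`, bundled value 18,367,558,099 AUD);
the report always returns the formula's product and flags any relative
discrepancy above 1e-6 — here ≈ −1.97 billion AUD (−10.7%) — instead of
adopting the reference figure. Currency conversion is a single
multiplication by the configured rate (default 0.71 USD/AUD).

## Scope and problem sizes

The test suite and acceptance script run the four-row reference table, a
31-point risk sweep, 51–101-point time grids, and ~20–50 randomized draws
per dynamics property; each completes in seconds, and the pipeline is
entirely deterministic (no seeds enter any reported quantity).

## Limitations

- No finite-population or stochastic dynamics, no networks or multi-player
  structure, no concrete social-norm model (interface only).
- No uncertainty propagation or sensitivity distributions over the QALY
  value; one-dimensional sweeps are the supported sensitivity tool.
- No stage-weighted QALY losses, no discounting, no empirical estimation
  from registry data.
- The synthetic scenarios exercise the arithmetic and the dynamics; passing
  tests show internal consistency with the stated formulas and published
  table, not predictive validity for real adoption behaviour.
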