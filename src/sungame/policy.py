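"""Policy analysis: minimum subsidies, regime flips, and parameter sweeps.

The key policy lever is a subsidy s on the private cost of sunscreen use.
Adoption becomes the stable outcome exactly when s > C - B, so the minimum
effective subsidy is s* = max(0, C - B); at s = s* the dynamics sit on the
neutral boundary and flipping requires strictly exceeding s*.

One-dimensional sweeps recompute the full calibration over a parameter grid
and locate regime boundaries (sign changes of B - C or B + E - C) by
bisection, which is cross-checked against closed-form thresholds where they
exist (risk thresholds, theta* = C / (B+E), s* = C - B).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.optimize import brentq

from .calibration import (
    DerivedQuantities,
    EconomicInputs,
    RegimeLabel,
    classify_regime,
    derive_quantities,
)
from .game import PayoffParameters

__all__ = [
    "SubsidyAnalysis",
    "Boundary",
    "SweepResult",
    "min_subsidy",
    "apply_subsidy",
    "analyze_subsidy",
    "sweep_parameter",
]


def min_subsidy(b: float, c: float) -> float:
    """Minimum subsidy making adoption privately rational, max(0, C - B).

    Works on either full-precision values or table-rounded integers; on
    integers it returns the integer C_r - B_r the display table reports.
    """
    if b < 0 or c < 0:
        raise ValueError("benefit and cost must be non-negative")
    return max(0, c - b)


def apply_subsidy(params: PayoffParameters, s: float) -> PayoffParameters:
    """Add a subsidy on top of any already in place.

    The resulting replicator coefficient is B - C + (s_old + s); applying
    s1 then s2 equals applying s1 + s2 at once.
    """
    if s < 0:
        raise ValueError("subsidy must be non-negative")
    return PayoffParameters(
        benefit=params.benefit,
        cost=params.cost,
        externality=params.externality,
        subsidy=params.subsidy + s,
    )


@dataclass(frozen=True)
class SubsidyAnalysis:
    """Minimum subsidy and the regimes just below and above it."""

    s_star: float
    pre_regime: RegimeLabel
    post_regime: RegimeLabel
    flipped: bool


def analyze_subsidy(b: float, e: float, c: float, bump: float = 1.0) -> SubsidyAnalysis:
    """Minimum subsidy s* and the regime at s = s* + ``bump``.

    ``bump`` defaults to 1 AUD, the smallest increment on the integer-AUD
    display scale; any positive value strictly above s* flips a non-adoption
    regime to private adoption.
    """
    if bump <= 0:
        raise ValueError("bump must be positive")
    s_star = min_subsidy(b, c)
    pre = classify_regime(b, e, c)
    post = classify_regime(b, e, c - (s_star + bump))
    flipped = (
        pre is not RegimeLabel.PRIVATE_ADOPTION
        and post is RegimeLabel.PRIVATE_ADOPTION
    )
    return SubsidyAnalysis(s_star=s_star, pre_regime=pre, post_regime=post, flipped=flipped)


@dataclass(frozen=True)
class Boundary:
    """A parameter value where a regime comparison changes sign."""

    comparison: str  # "private" (B - C) | "social" (B + E - C)
    value: float


@dataclass(frozen=True)
class SweepResult:
    """Calibration outcomes over a one-dimensional parameter grid."""

    parameter: str
    frame: pd.DataFrame
    boundaries: tuple[Boundary, ...]


def _comparison_value(inputs: EconomicInputs, name: str, value: float, which: str) -> float:
    d = derive_quantities(inputs.model_copy(update={name: value}))
    if which == "private":
        return d.b_private - d.c_lifetime
    return d.total_benefit - d.c_lifetime


def sweep_parameter(
    inputs: EconomicInputs, name: str, grid: Sequence[float]
) -> SweepResult:
    """Recompute the calibration across ``grid`` values of one input field.

    Regime boundaries are bracketed between adjacent grid values where the
    private (B - C) or social (B + E - C) comparison changes sign, then
    refined by bisection to 1e-8 of the grid span.
    """
    sweepable = sorted(EconomicInputs.model_fields)
    if name not in sweepable:
        raise ValueError(
            f"unknown sweep parameter {name!r}; sweepable parameters: {', '.join(sweepable)}"
        )
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")

    rows = []
    for v in grid:
        d = derive_quantities(inputs.model_copy(update={name: v}))
        rows.append(
            {
                "value": v,
                "total_benefit": d.total_benefit,
                "b_private": d.b_private,
                "e_external": d.e_external,
                "c_lifetime": d.c_lifetime,
                "regime": d.regime.value,
                "s_star": d.s_star,
            }
        )
    frame = pd.DataFrame(rows)

    span = max(grid) - min(grid)
    xtol = max(1e-8 * span, 1e-300)
    boundaries: list[Boundary] = []
    for which in ("private", "social"):
        signs = [_comparison_value(inputs, name, v, which) for v in grid]
        for i in range(len(grid) - 1):
            a, b = signs[i], signs[i + 1]
            if a == 0.0:
                boundaries.append(Boundary(which, float(grid[i])))
            elif a * b < 0.0:
                root = brentq(
                    lambda v: _comparison_value(inputs, name, v, which),
                    grid[i],
                    grid[i + 1],
                    xtol=xtol,
                )
                boundaries.append(Boundary(which, float(root)))
        if len(grid) >= 2 and signs[-1] == 0.0:
            boundaries.append(Boundary(which, float(grid[-1])))

    return SweepResult(parameter=name, frame=frame, boundaries=tuple(boundaries))
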