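"""Economic calibration pipeline: scenario parameters to game payoffs.

Maps a set of health-economic inputs (lifetime melanoma risk, relative risk
under daily sunscreen use, treatment cost, monetized QALY loss, sunscreen
price and usage, horizon, private cost share) to the game's primitives:

* lifetime sunscreen cost  C = (price / volume) * mL/day * days/year * years
* per-case monetized loss  K = K_med + V * dQALY
* total prevention benefit B + E = p (1 - RR) K
* private/external split   B = theta (B+E),  E = (1 - theta) (B+E)
* minimum subsidy          s* = max(0, C - B)

All arithmetic runs at full precision; display tables round half-up to
integer AUD and compute s* on the rounded integers, which is the convention
the reference scenario's published table follows.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "EconomicInputs",
    "RegimeLabel",
    "DerivedQuantities",
    "RiskThresholds",
    "ScenarioTable",
    "round_half_up",
    "price_per_ml",
    "lifetime_cost",
    "per_case_loss",
    "prevention_benefit_total",
    "split_private_social",
    "classify_regime",
    "risk_thresholds",
    "derive_quantities",
    "build_scenario_table",
]


def round_half_up(value: float) -> int:
    """Round a non-negative amount to the nearest integer, ties away from zero."""
    if value < 0:
        raise ValueError("round_half_up expects a non-negative value")
    return int(math.floor(value + 0.5))


class EconomicInputs(BaseModel):
    """Scenario parameters for one population.

    Field names double as the scenario-config keys, so a config round-trips
    losslessly.  Units: monetary values in AUD; ``p`` and ``theta`` are
    probabilities/shares in [0, 1]; ``rr`` is the relative risk of melanoma
    under daily sunscreen use (benefit scales with ``1 - rr``).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    p: float = Field(ge=0, le=1, description="lifetime melanoma risk")
    rr: float = Field(ge=0, le=1, description="relative risk with daily sunscreen")
    k_med: float = Field(ge=0, description="direct medical cost per case, AUD")
    v_per_qaly: float = Field(ge=0, description="monetary value per QALY, AUD")
    dqaly: float = Field(ge=0, description="QALY loss per case")
    price: float = Field(ge=0, description="sunscreen retail price, AUD per bottle")
    volume_ml: float = Field(gt=0, description="bottle volume, mL")
    ml_per_day: float = Field(ge=0, description="application quantity, mL/day")
    days_per_year: float = Field(ge=0, description="sunny days per year")
    years: float = Field(ge=0, description="horizon, summers")
    theta: float = Field(ge=0, le=1, description="private share of the per-case loss")


class RegimeLabel(str, enum.Enum):
    """Joint classification of private incentive and social efficiency."""

    PRIVATE_ADOPTION = "private_adoption"
    EFFICIENT_NON_ADOPTION = "efficient_non_adoption"
    INEFFICIENT_NON_ADOPTION = "inefficient_non_adoption"
    NEUTRAL_BOUNDARY = "neutral_boundary"


@dataclass(frozen=True)
class DerivedQuantities:
    """Full-precision derived quantities for one risk scenario (AUD)."""

    p: float
    price_per_ml: float
    c_lifetime: float
    k_total: float
    total_benefit: float  # B + E
    b_private: float
    e_external: float
    s_star: float  # max(0, C - B), full precision
    regime: RegimeLabel


def price_per_ml(price: float, volume_ml: float) -> float:
    """Sunscreen price per millilitre, full precision."""
    if volume_ml <= 0:
        raise ValueError(f"volume_ml must be positive, got {volume_ml!r}")
    return price / volume_ml


def lifetime_cost(inputs: EconomicInputs) -> float:
    """Lifetime private sunscreen cost C over the scenario horizon, AUD."""
    return (
        price_per_ml(inputs.price, inputs.volume_ml)
        * inputs.ml_per_day
        * inputs.days_per_year
        * inputs.years
    )


def per_case_loss(k_med: float, v_per_qaly: float, dqaly: float) -> float:
    """Total monetized loss per melanoma case, K = K_med + V * dQALY."""
    if min(k_med, v_per_qaly, dqaly) < 0:
        raise ValueError("per-case loss components must be non-negative")
    return k_med + v_per_qaly * dqaly


def prevention_benefit_total(p: float, rr: float, k_total: float) -> float:
    """Expected prevented loss per person, B + E = p (1 - RR) K."""
    if not (0 <= p <= 1 and 0 <= rr <= 1):
        raise ValueError("p and rr must lie in [0, 1]")
    return p * (1.0 - rr) * k_total


def split_private_social(total: float, theta: float) -> tuple[float, float]:
    """Split the total benefit into private and external parts.

    Returns ``(B, E)`` with ``B = theta * total`` and ``E = total - B``, so
    the split conserves the total exactly in floating point.
    """
    if not 0 <= theta <= 1:
        raise ValueError("theta must lie in [0, 1]")
    b = theta * total
    return b, total - b


def classify_regime(b: float, e: float, c: float) -> RegimeLabel:
    """Classify private incentive (B vs C) against social efficiency (B+E vs C).

    Exact ties on either comparison map to ``NEUTRAL_BOUNDARY`` rather than
    being silently assigned to a side.
    """
    total = b + e
    if b == c or total == c:
        return RegimeLabel.NEUTRAL_BOUNDARY
    if b > c:
        return RegimeLabel.PRIVATE_ADOPTION
    if total < c:
        return RegimeLabel.EFFICIENT_NON_ADOPTION
    return RegimeLabel.INEFFICIENT_NON_ADOPTION


@dataclass(frozen=True)
class RiskThresholds:
    """Risk levels where the social and private comparisons change sign.

    A threshold above 1 cannot be reached by any population and is flagged
    ``unreachable``.
    """

    p_social: float
    p_private: float
    p_social_reachable: bool
    p_private_reachable: bool


def risk_thresholds(inputs: EconomicInputs) -> RiskThresholds:
    """Closed-form risk thresholds.

    ``p_social = C / ((1-RR) K)`` solves B+E = C; ``p_private = C / (theta
    (1-RR) K)`` solves B = C.  ``theta = 0`` makes the private threshold
    infinite (no private benefit at any risk).
    """
    k = per_case_loss(inputs.k_med, inputs.v_per_qaly, inputs.dqaly)
    c = lifetime_cost(inputs)
    denom = (1.0 - inputs.rr) * k
    if denom <= 0:
        raise ValueError(
            "degenerate scenario: (1 - rr) * K must be positive to define risk thresholds"
        )
    p_social = c / denom
    p_private = c / (inputs.theta * denom) if inputs.theta > 0 else math.inf
    return RiskThresholds(
        p_social=p_social,
        p_private=p_private,
        p_social_reachable=p_social <= 1.0,
        p_private_reachable=p_private <= 1.0,
    )


def derive_quantities(inputs: EconomicInputs, p: float | None = None) -> DerivedQuantities:
    """Run the full calibration at risk ``p`` (default: the scenario's own)."""
    risk = inputs.p if p is None else p
    ppm = price_per_ml(inputs.price, inputs.volume_ml)
    c = lifetime_cost(inputs)
    k = per_case_loss(inputs.k_med, inputs.v_per_qaly, inputs.dqaly)
    total = prevention_benefit_total(risk, inputs.rr, k)
    b, e = split_private_social(total, inputs.theta)
    return DerivedQuantities(
        p=risk,
        price_per_ml=ppm,
        c_lifetime=c,
        k_total=k,
        total_benefit=total,
        b_private=b,
        e_external=e,
        s_star=max(0.0, c - b),
        regime=classify_regime(b, e, c),
    )


_PRIVATE_SIGN = {1: "B>C", 0: "B=C", -1: "B<C"}
_SOCIAL_SIGN = {1: "B+E>C", 0: "B+E=C", -1: "B+E<C"}


@dataclass(frozen=True)
class ScenarioTable:
    """Per-risk calibration table rendered in integer AUD.

    ``frame`` carries the nine display columns (risk, rounded AUD cells,
    incentive/efficiency signs, regime, minimum subsidy) plus full-precision
    companion columns suffixed ``_exact``.  The minimum subsidy is computed
    on the rounded integers, ``s* = C_r - B_r`` floored at 0.
    """

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.frame.to_json(path, orient="records", indent=2)


def build_scenario_table(
    inputs: EconomicInputs, risks: Sequence[float]
) -> ScenarioTable:
    """Build the calibration table, one row per risk level.

    Regime labels are assigned on the full-precision comparisons; only the
    displayed cells are rounded.
    """
    if len(risks) == 0:
        raise ValueError("at least one risk level is required")
    rows = []
    for p in risks:
        d = derive_quantities(inputs, p=p)
        b_r = round_half_up(d.b_private)
        c_r = round_half_up(d.c_lifetime)
        rows.append(
            {
                "p": p,
                "total_benefit_aud": round_half_up(d.total_benefit),
                "private_benefit_aud": b_r,
                "external_benefit_aud": round_half_up(d.e_external),
                "lifetime_cost_aud": c_r,
                "private_incentive": _PRIVATE_SIGN[_sign(d.b_private - d.c_lifetime)],
                "social_efficiency": _SOCIAL_SIGN[_sign(d.total_benefit - d.c_lifetime)],
                "regime": d.regime.value,
                "min_subsidy_aud": max(0, c_r - b_r),
                "total_benefit_exact": d.total_benefit,
                "private_benefit_exact": d.b_private,
                "external_benefit_exact": d.e_external,
                "lifetime_cost_exact": d.c_lifetime,
            }
        )
    return ScenarioTable(frame=pd.DataFrame(rows))


def _sign(v: float) -> int:
    return 0 if v == 0 else (1 if v > 0 else -1)
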