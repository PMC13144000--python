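"""Aggregate public-cost estimate for a high-risk demographic cohort.

The burden model is a deliberately simple cohort product: population size
times the age, sex and risk shares, times an average treatment cost per
case, assuming one treated case per high-risk cohort member.  A currency
conversion turns the AUD total into a foreign-currency headline figure.

The cohort spec may carry an externally reported reference total
(``headline_total_aud``); the report then compares the computed product
against it and flags any material discrepancy instead of silently adopting
the reference figure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "CohortSpec",
    "BurdenEstimate",
    "aggregate_burden",
    "convert_currency",
    "burden_report",
]


class CohortSpec(BaseModel):
    """Demographic cohort and per-case cost for the burden product."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    population: float = Field(ge=0, description="total population, persons")
    share_age: float = Field(ge=0, le=1, description="proportion in the age bracket")
    share_sex: float = Field(ge=0, le=1, description="proportion of the target sex within it")
    share_risk: float = Field(ge=0, le=1, description="proportion at elevated melanoma risk")
    cost_per_case: float = Field(ge=0, description="average treatment cost per case, AUD")
    headline_total_aud: Optional[float] = Field(
        default=None,
        ge=0,
        description="externally reported reference total to cross-check, AUD",
    )


def aggregate_burden(spec: CohortSpec) -> float:
    """Plain product of the five cohort factors, in AUD."""
    return (
        spec.population
        * spec.share_age
        * spec.share_sex
        * spec.share_risk
        * spec.cost_per_case
    )


def convert_currency(amount: float, rate: float) -> float:
    """Convert an AUD amount at ``rate`` foreign-currency units per AUD."""
    if rate <= 0:
        raise ValueError(f"conversion rate must be positive, got {rate!r}")
    return amount * rate


@dataclass(frozen=True)
class BurdenEstimate:
    """Computed burden with conversion and optional reference cross-check."""

    total_aud: float
    total_converted: float
    rate: float
    factors: tuple[float, ...]
    headline_total_aud: float | None = None
    headline_discrepancy_aud: float | None = None
    headline_discrepant: bool = False

    def to_dict(self) -> dict:
        return {
            "total_aud": self.total_aud,
            "total_converted": self.total_converted,
            "rate": self.rate,
            "factors": list(self.factors),
            "headline_total_aud": self.headline_total_aud,
            "headline_discrepancy_aud": self.headline_discrepancy_aud,
            "headline_discrepant": self.headline_discrepant,
        }


def burden_report(
    spec: CohortSpec, rate: float = 0.71, rel_tol: float = 1e-6
) -> BurdenEstimate:
    """Full burden report: AUD total, converted total, and reference check.

    If the spec carries a reference headline total, the report records the
    absolute discrepancy and flags it when the relative difference exceeds
    ``rel_tol`` — the computed product is always what the formula yields,
    never the reference figure.
    """
    total = aggregate_burden(spec)
    discrepancy = None
    discrepant = False
    if spec.headline_total_aud is not None:
        discrepancy = total - spec.headline_total_aud
        denom = max(abs(spec.headline_total_aud), 1.0)
        discrepant = abs(discrepancy) / denom > rel_tol
    return BurdenEstimate(
        total_aud=total,
        total_converted=convert_currency(total, rate),
        rate=rate,
        factors=(
            spec.population,
            spec.share_age,
            spec.share_sex,
            spec.share_risk,
            spec.cost_per_case,
        ),
        headline_total_aud=spec.headline_total_aud,
        headline_discrepancy_aud=discrepancy,
        headline_discrepant=discrepant,
    )
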