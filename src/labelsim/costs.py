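"""Obesity-cost projection, discounting and label-induced savings.

Baseline direct (health-system) and indirect (productivity and premature
death) obesity costs are stated in Mexican pesos at a base year, restated
to the policy start year with a national CPI deflator, discounted at a
yearly rate over the 5-year horizon, and converted to US dollars at the
policy-year average exchange rate.  Savings multiply the yearly absolute
obesity-prevalence reductions by the yearly costs; the benefit-cost ratio
divides total savings by the label's implementation cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CostInputs",
    "CostStream",
    "Savings",
    "benefit_cost_ratio",
    "project_costs",
    "savings",
    "DEFAULT_DEFLATOR",
]

#: Approximate Mexican national consumer-price index, annual averages
#: (2018 second fortnight of July = 100). Illustrative series for the
#: deflator path; supply the official INEGI series for production use.
DEFAULT_DEFLATOR: dict[int, float] = {
    2014: 83.97,
    2015: 86.25,
    2016: 88.69,
    2017: 94.04,
    2018: 98.99,
    2019: 102.58,
}

_DISCOUNT_RATE = 0.03
_FX_MXP_TO_USD = 0.05190017
_IMPLEMENTATION_COST_MUSD = 312.6


@dataclass
class CostInputs:
    """Baseline obesity costs and the projection conventions.

    ``base_direct_mxp`` / ``base_indirect_mxp`` are annual costs in million
    MXP at ``base_year``; ``fx_rate_mxp_to_usd`` is the policy-year average
    exchange rate; ``implementation_cost_usd`` is in million USD.
    """

    base_direct_mxp: float
    base_indirect_mxp: float
    base_year: int = 2014
    start_year: int = 2019
    deflator: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_DEFLATOR))
    discount_rate: float = _DISCOUNT_RATE
    fx_rate_mxp_to_usd: float = _FX_MXP_TO_USD
    implementation_cost_usd: float = _IMPLEMENTATION_COST_MUSD
    horizon_years: int = 5

    def validate(self) -> None:
        if not 0.0 <= self.discount_rate <= 0.2:
            raise ValueError(f"discount_rate must be in [0, 0.2], got {self.discount_rate}")
        if not self.fx_rate_mxp_to_usd > 0:
            raise ValueError("fx_rate_mxp_to_usd must be > 0")
        if self.base_direct_mxp < 0 or self.base_indirect_mxp < 0:
            raise ValueError("baseline costs must be nonnegative")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")
        for year in (self.base_year, self.start_year):
            if year not in self.deflator:
                raise ValueError(f"deflator series missing year {year}")

    @classmethod
    def from_usd_totals(
        cls,
        direct_total_usd: float,
        indirect_total_usd: float,
        discount_rate: float = _DISCOUNT_RATE,
        fx_rate_mxp_to_usd: float = _FX_MXP_TO_USD,
        implementation_cost_usd: float = _IMPLEMENTATION_COST_MUSD,
        horizon_years: int = 5,
        start_year: int = 2019,
    ) -> "CostInputs":
        """Build inputs whose discounted 5-year USD totals match given sums.

        Inverts the discount annuity: year-1 cost = total / sum_k (1+r)^-k.
        Useful when only horizon totals (already in start-year USD) are
        published.
        """
        annuity = sum((1.0 + discount_rate) ** -k for k in range(horizon_years))
        flat = {start_year: 1.0}
        return cls(
            base_direct_mxp=direct_total_usd / annuity / fx_rate_mxp_to_usd,
            base_indirect_mxp=indirect_total_usd / annuity / fx_rate_mxp_to_usd,
            base_year=start_year,
            start_year=start_year,
            deflator=flat,
            discount_rate=discount_rate,
            fx_rate_mxp_to_usd=fx_rate_mxp_to_usd,
            implementation_cost_usd=implementation_cost_usd,
            horizon_years=horizon_years,
        )


@dataclass(frozen=True)
class CostStream:
    """Yearly direct and indirect obesity costs in start-year million USD."""

    years: np.ndarray
    direct_usd: np.ndarray
    indirect_usd: np.ndarray

    @property
    def total_usd(self) -> np.ndarray:
        return self.direct_usd + self.indirect_usd

    @property
    def totals(self) -> dict[str, float]:
        return {
            "direct": float(self.direct_usd.sum()),
            "indirect": float(self.indirect_usd.sum()),
            "total": float(self.total_usd.sum()),
        }


@dataclass(frozen=True)
class Savings:
    """Label-induced cost reductions over the horizon (million USD)."""

    direct: float
    indirect: float

    @property
    def total(self) -> float:
        return self.direct + self.indirect


def project_costs(inputs: CostInputs) -> CostStream:
    """Deflate baseline costs to the start year, then discount yearly.

    Year-1 cost = base cost x (deflator_start / deflator_base); year k > 1
    cost = year-1 cost x (1 + r)^-(k-1).  MXP -> USD conversion is applied
    last.
    """
    inputs.validate()
    ratio = inputs.deflator[inputs.start_year] / inputs.deflator[inputs.base_year]
    k = np.arange(inputs.horizon_years)
    disc = (1.0 + inputs.discount_rate) ** -k
    fx = inputs.fx_rate_mxp_to_usd
    return CostStream(
        years=inputs.start_year + k,
        direct_usd=inputs.base_direct_mxp * ratio * disc * fx,
        indirect_usd=inputs.base_indirect_mxp * ratio * disc * fx,
    )


def savings(prev_changes_pp: Sequence[float], stream: CostStream) -> Savings:
    """Cost reductions from yearly absolute prevalence reductions.

    ``prev_changes_pp`` holds one end-of-year prevalence reduction (in
    percentage points, positive = reduction) per horizon year; each
    component saving is sum_t (pp_t / 100) x cost_t.
    """
    pp = np.asarray(prev_changes_pp, float)
    if pp.shape != stream.direct_usd.shape:
        raise ValueError(
            f"expected {stream.direct_usd.shape[0]} yearly prevalence changes, got {pp.shape[0]}"
        )
    frac = pp / 100.0
    return Savings(
        direct=float((frac * stream.direct_usd).sum()),
        indirect=float((frac * stream.indirect_usd).sum()),
    )


def benefit_cost_ratio(total_savings_usd: float, implementation_cost_usd: float) -> float:
    """Savings produced per dollar of implementation spending."""
    if not implementation_cost_usd > 0:
        raise ValueError("implementation_cost_usd must be > 0")
    return total_savings_usd / implementation_cost_usd
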