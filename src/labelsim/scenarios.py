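"""Warning-label effect scenarios and per-person intake deltas.

A :class:`Scenario` carries fractional changes in daily energy and sodium
from labelled beverages and snacks.  The main scenario uses experimental
"high in" warning-label effects (beverages −10.5% kcal, snacks −3.0% kcal;
sodium −7.6% / −8.3%); sensitivity scenarios use Chilean observational
estimates (aggregate −7.5%; stratified −27.5% for "high in" and +10.8% for
"not high in" beverages under Chilean or Mexican nutrient limits) and a
Uruguayan snack experiment (−11.68% kcal, −50.17% sodium).

Stratified scenarios need a "high in" share of category energy; the legal
nutrient limits that would determine that share product-by-product live in
:class:`NutrientThresholds`, applied by :func:`classify_product`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "IntakeDelta",
    "NutrientThresholds",
    "Scenario",
    "builtin_scenarios",
    "classify_product",
    "effective_fractions",
    "load_thresholds_csv",
    "scenario_delta",
    "scenario_deltas",
    "ILLUSTRATIVE_THRESHOLDS",
]

LABEL_NUTRIENTS = ("energy_kcal", "sugars_g", "saturated_fat_g", "trans_fat_g", "sodium_mg")


@dataclass(frozen=True)
class NutrientThresholds:
    """Per-100 g / per-100 mL legal limits for "excess of" labels.

    ``jurisdiction`` tags the rule set (e.g. ``chile_stage1``, ``mexico``).
    A nutrient with no limit defined is never flagged.  Comparison
    convention is strict by default: a label applies when the amount
    exceeds the limit (``strict=False`` switches to >=).
    """

    jurisdiction: str
    per_100g: Mapping[str, float] = field(default_factory=dict)
    per_100ml: Mapping[str, float] = field(default_factory=dict)
    strict: bool = True

    def __post_init__(self) -> None:
        if not self.per_100g and not self.per_100ml:
            raise ValueError("at least one limit must be defined")
        for table in (self.per_100g, self.per_100ml):
            for nutrient, limit in table.items():
                if limit < 0:
                    raise ValueError(f"negative limit for {nutrient!r}: {limit}")

    def limits_for(self, basis: str) -> Mapping[str, float]:
        if basis == "solid":
            table = self.per_100g
        elif basis == "liquid":
            table = self.per_100ml
        else:
            raise ValueError(f"basis must be 'solid' or 'liquid', got {basis!r}")
        if not table:
            raise ValueError(
                f"unit-basis mismatch: {basis} profile but thresholds "
                f"{self.jurisdiction!r} define no {basis} limits"
            )
        return table


#: Editable illustrative limits. The official per-100g/per-100mL values of
#: the Chilean stage-1 and Mexican rules should be supplied from the legal
#: texts (config or CSV); these placeholders only exercise the machinery.
ILLUSTRATIVE_THRESHOLDS: dict[str, NutrientThresholds] = {
    "chile_stage1": NutrientThresholds(
        jurisdiction="chile_stage1",
        per_100g={"energy_kcal": 350.0, "sugars_g": 22.5, "saturated_fat_g": 6.0, "sodium_mg": 800.0},
        per_100ml={"energy_kcal": 100.0, "sugars_g": 6.0, "saturated_fat_g": 3.0, "sodium_mg": 100.0},
    ),
    "mexico": NutrientThresholds(
        jurisdiction="mexico",
        per_100g={"energy_kcal": 275.0, "sugars_g": 10.0, "saturated_fat_g": 4.0,
                  "trans_fat_g": 0.3, "sodium_mg": 300.0},
        per_100ml={"energy_kcal": 70.0, "sugars_g": 5.0, "saturated_fat_g": 3.0,
                   "trans_fat_g": 0.3, "sodium_mg": 45.0},
    ),
}


@dataclass(frozen=True)
class Scenario:
    """Fractional intake changes attributed to warning labels.

    Fractions are applied multiplicatively to each person's category intake
    (negative = reduction) and lie in (−1, 1].  In ``stratified`` mode the
    beverage change splits into ``highin_frac`` on the "high in" share of
    beverage energy and ``not_highin_frac`` on the rest; snacks stay in
    aggregate mode.
    """

    name: str
    beverage_kcal_frac: float = 0.0
    snack_kcal_frac: float = 0.0
    beverage_sodium_frac: float = 0.0
    snack_sodium_frac: float = 0.0
    mode: str = "aggregate"
    highin_frac: float | None = None
    not_highin_frac: float | None = None
    thresholds: NutrientThresholds | None = None
    highin_share: float = 0.80

    def __post_init__(self) -> None:
        if self.mode not in ("aggregate", "stratified"):
            raise ValueError(f"mode must be 'aggregate' or 'stratified', got {self.mode!r}")
        fracs = [self.beverage_kcal_frac, self.snack_kcal_frac,
                 self.beverage_sodium_frac, self.snack_sodium_frac]
        if self.mode == "stratified":
            if self.highin_frac is None or self.not_highin_frac is None:
                raise ValueError("stratified mode requires highin_frac and not_highin_frac")
            if self.thresholds is None:
                raise ValueError("stratified mode requires nutrient thresholds")
            if not 0.0 <= self.highin_share <= 1.0:
                raise ValueError("highin_share must lie in [0, 1]")
            fracs += [self.highin_frac, self.not_highin_frac]
        for f in fracs:
            if not -1.0 < f <= 1.0:
                raise ValueError(f"scenario fraction {f} outside (-1, 1]")


@dataclass(frozen=True)
class IntakeDelta:
    """Per-person daily change in energy and sodium under a scenario."""

    person_id: object
    d_beverage_kcal: float
    d_snack_kcal: float
    d_total_kcal: float
    d_sodium_mg: float

    def __post_init__(self) -> None:
        if self.d_total_kcal != self.d_beverage_kcal + self.d_snack_kcal:
            raise ValueError("d_total_kcal must equal d_beverage_kcal + d_snack_kcal")


def builtin_scenarios() -> list[Scenario]:
    """The main scenario and the published sensitivity scenarios.

    Beverage-axis sensitivity scenarios keep snacks at the main-scenario
    values (and vice versa), so each scenario varies one axis at a time.
    """
    main = Scenario(
        name="main_canada",
        beverage_kcal_frac=-0.105,
        snack_kcal_frac=-0.030,
        beverage_sodium_frac=-0.076,
        snack_sodium_frac=-0.083,
    )
    chile_aggregate = replace(
        main, name="chile_aggregate", beverage_kcal_frac=-0.075, beverage_sodium_frac=0.0
    )
    chile_strat = Scenario(
        name="chile_stratified_chile_limits",
        snack_kcal_frac=-0.030,
        snack_sodium_frac=-0.083,
        mode="stratified",
        highin_frac=-0.275,
        not_highin_frac=0.108,
        thresholds=ILLUSTRATIVE_THRESHOLDS["chile_stage1"],
        highin_share=0.80,
    )
    chile_strat_mx = replace(
        chile_strat,
        name="chile_stratified_mexico_limits",
        thresholds=ILLUSTRATIVE_THRESHOLDS["mexico"],
        highin_share=0.90,  # stricter limits label more beverages
    )
    uruguay = replace(
        main, name="uruguay_snacks", snack_kcal_frac=-0.1168, snack_sodium_frac=-0.5017
    )
    return [main, chile_aggregate, chile_strat, chile_strat_mx, uruguay]


def get_scenario(name: str) -> Scenario:
    """Look up a built-in scenario by name (``"null"`` = no label effect)."""
    if name == "null":
        return Scenario(name="null")
    for sc in builtin_scenarios():
        if sc.name == name:
            return sc
    known = ", ".join(s.name for s in builtin_scenarios())
    raise KeyError(f"unknown scenario {name!r}; built-ins: {known}, null")


def classify_product(
    profile: Mapping[str, float],
    thresholds: NutrientThresholds,
    basis: str = "solid",
) -> dict[str, bool]:
    """Flag which "excess of" labels a product profile would carry.

    ``profile`` maps nutrient names to amounts per 100 g (``basis='solid'``)
    or per 100 mL (``basis='liquid'``).  A nutrient is flagged iff a limit is
    defined for it and the amount exceeds the limit (strictly, by default);
    ``any_label`` is the OR over nutrient flags.
    """
    limits = thresholds.limits_for(basis)
    flags: dict[str, bool] = {}
    for nutrient, amount in profile.items():
        if amount < 0:
            raise ValueError(f"negative amount for {nutrient!r}: {amount}")
        if nutrient in limits:
            limit = limits[nutrient]
            flags[nutrient] = amount > limit if thresholds.strict else amount >= limit
        else:
            flags[nutrient] = False
    flags["any_label"] = any(v for k, v in flags.items() if k != "any_label")
    return flags


def effective_fractions(scenario: Scenario, highin_share: float | None = None) -> tuple[float, float]:
    """Effective (beverage, snack) kcal fractions, resolving stratification.

    In stratified mode the beverage fraction is the share-weighted blend
    ``highin_frac*s + not_highin_frac*(1-s)``.
    """
    if scenario.mode == "aggregate":
        return scenario.beverage_kcal_frac, scenario.snack_kcal_frac
    s = scenario.highin_share if highin_share is None else highin_share
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"highin_share must lie in [0, 1], got {s}")
    bev = scenario.highin_frac * s + scenario.not_highin_frac * (1.0 - s)
    return bev, scenario.snack_kcal_frac


def scenario_deltas(
    cohort: pd.DataFrame,
    scenario: Scenario,
    highin_share: float | None = None,
) -> pd.DataFrame:
    """Vectorized per-person intake deltas for a cohort frame.

    Returns a frame aligned with ``cohort`` carrying beverage/snack kcal and
    sodium deltas plus their totals; ``d_total_kcal`` is exactly the sum of
    the two kcal components.
    """
    bev_f, snk_f = effective_fractions(scenario, highin_share)
    d_bev = bev_f * cohort["beverage_kcal"].to_numpy(float)
    d_snk = snk_f * cohort["snack_kcal"].to_numpy(float)
    d_bev_na = scenario.beverage_sodium_frac * cohort["beverage_sodium_mg"].to_numpy(float)
    d_snk_na = scenario.snack_sodium_frac * cohort["snack_sodium_mg"].to_numpy(float)
    return pd.DataFrame(
        {
            "person_id": cohort["person_id"].to_numpy(),
            "d_beverage_kcal": d_bev,
            "d_snack_kcal": d_snk,
            "d_total_kcal": d_bev + d_snk,
            "d_beverage_sodium_mg": d_bev_na,
            "d_snack_sodium_mg": d_snk_na,
            "d_sodium_mg": d_bev_na + d_snk_na,
        }
    )


def scenario_delta(
    record: Mapping[str, float] | pd.Series,
    scenario: Scenario,
    highin_share: float | None = None,
) -> IntakeDelta:
    """Intake delta for a single individual record."""
    for key in ("beverage_kcal", "snack_kcal"):
        if record[key] < 0:
            raise ValueError(f"record has negative {key}: {record[key]}")
    bev_f, snk_f = effective_fractions(scenario, highin_share)
    d_bev = bev_f * float(record["beverage_kcal"])
    d_snk = snk_f * float(record["snack_kcal"])
    d_na = scenario.beverage_sodium_frac * float(record.get("beverage_sodium_mg", 0.0)) + (
        scenario.snack_sodium_frac * float(record.get("snack_sodium_mg", 0.0))
    )
    return IntakeDelta(
        person_id=record.get("person_id"),
        d_beverage_kcal=d_bev,
        d_snack_kcal=d_snk,
        d_total_kcal=d_bev + d_snk,
        d_sodium_mg=d_na,
    )


def load_thresholds_csv(path, jurisdiction: str, strict: bool = True) -> NutrientThresholds:
    """Load nutrient limits from CSV with columns nutrient, basis, limit, unit.

    ``basis`` is ``solid`` (per 100 g) or ``liquid`` (per 100 mL); ``unit``
    is informational.
    """
    df = pd.read_csv(path)
    required = {"nutrient", "basis", "limit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"thresholds CSV missing column(s): {sorted(missing)}")
    per: dict[str, dict[str, float]] = {"solid": {}, "liquid": {}}
    for _, row in df.iterrows():
        basis = str(row["basis"]).strip().lower()
        if basis not in per:
            raise ValueError(f"unknown basis {row['basis']!r} (expected solid/liquid)")
        per[basis][str(row["nutrient"]).strip()] = float(row["limit"])
    return NutrientThresholds(
        jurisdiction=jurisdiction, per_100g=per["solid"], per_100ml=per["liquid"], strict=strict
    )
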