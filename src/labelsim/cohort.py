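"""Seeded synthetic adult cohorts emulating a national nutrition survey.

The generator produces cohorts of Mexican adults aged 20-59 whose
survey-weighted moments match published marginal targets: mean daily energy
from labelled beverages and snacks, mean body weight and BMI, obesity
prevalence, and a survey-weight total equal to the represented adult
population.  The cohort is a :class:`pandas.DataFrame` with one row per
individual (see :data:`COHORT_COLUMNS`), carrying the survey-design fields
(stratum and primary sampling unit) needed for design-based inference.

Calibration works distribution-first: BMI follows a log-normal whose
parameters are solved in closed form from the target mean and obesity
prevalence; intakes follow right-skewed log-normals with subgroup
multipliers (younger, male and middle/high-SES adults consume more labelled
products) and are ratio-calibrated to the target weighted means.  A
randomized-systematic (Latin-hypercube) sampler keeps realized moments on
target at survey-scale n.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationError",
    "CalibrationTargets",
    "ExclusionReport",
    "IntakeMultipliers",
    "apply_exclusions",
    "generate_cohort",
    "COHORT_COLUMNS",
    "SEX_LEVELS",
    "SES_LEVELS",
]

SEX_LEVELS = ("female", "male")
SES_LEVELS = ("low", "middle", "high")

#: Column contract for a cohort frame (one row = one IndividualRecord).
COHORT_COLUMNS = (
    "person_id",
    "age",
    "sex",
    "ses",
    "height",
    "weight",
    "bmi",
    "beverage_kcal",
    "snack_kcal",
    "total_energy_kcal",
    "beverage_sodium_mg",
    "snack_sodium_mg",
    "beverage_servings",
    "survey_weight",
    "stratum_id",
    "psu_id",
)

#: Exclusion rules in evaluation order; a record counts under its first hit.
EXCLUSION_RULES = (
    "missing_weight_height",
    "bmi_ge_60",
    "servings_gt_16",
    "pregnant_lactating",  # report category only; never generated synthetically
)

BMI_IMPLAUSIBLE = 60.0
BMI_PLAUSIBLE_MIN = 16.0  # severe-thinness bound; survey plausibility floor
MAX_BEVERAGE_SERVINGS = 16.0


class CalibrationError(ValueError):
    """Targets are jointly infeasible or the generated cohort missed them."""


@dataclass(frozen=True)
class IntakeMultipliers:
    """Relative labelled-product intake by subgroup.

    Multipliers act on the log-normal scale factor for both beverage and
    snack intake; absolute levels are irrelevant because the weighted mean
    is ratio-calibrated afterwards.  Defaults make under-40, male and
    middle/high-SES adults the heavier consumers, so subgroup orderings of
    the obesity response can emerge.
    """

    age_under_40: float = 1.20
    age_40_59: float = 0.80
    male: float = 1.15
    female: float = 0.87
    ses_low: float = 0.85
    ses_middle: float = 1.05
    ses_high: float = 1.10

    def vector(self, age: np.ndarray, sex: np.ndarray, ses: np.ndarray) -> np.ndarray:
        m_age = np.where(age < 40, self.age_under_40, self.age_40_59)
        m_sex = np.where(sex == "female", self.female, self.male)
        ses_map = {"low": self.ses_low, "middle": self.ses_middle, "high": self.ses_high}
        m_ses = np.vectorize(ses_map.__getitem__, otypes=[float])(ses)
        return m_age * m_sex * m_ses


@dataclass
class CalibrationTargets:
    """Marginal calibration targets plus generator dispersion knobs.

    The headline targets default to the analytic-sample values of the 2016
    Mexican National Health and Nutrition Survey (ENSANUT) for adults
    20-59: labelled-beverage intake 220.9 kcal/day, labelled-snack intake
    453.1 kcal/day (together 31.1% of total energy), mean weight 72.38 kg,
    mean BMI 28.34 kg/m^2, obesity prevalence 33.81%, and survey weights
    summing to 48,289,840 represented adults.
    """

    mean_beverage_kcal: float = 220.9
    mean_snack_kcal: float = 453.1
    mean_weight_kg: float = 72.38
    mean_bmi: float = 28.34
    obesity_prevalence: float = 0.3381
    weighted_population: float = 48_289_840.0
    intake_share_of_energy: float = 0.311
    multipliers: IntakeMultipliers = field(default_factory=IntakeMultipliers)

    # dispersion / structure knobs (documented defaults; see docs/methods.md)
    intake_sigma_log: float = 1.0
    other_energy_sigma_log: float = 0.30
    survey_weight_sigma_log: float = 0.30
    female_fraction: float = 0.52
    ses_probs: tuple[float, float, float] = (0.33, 0.34, 0.33)
    mean_height_female: float = 1.55
    mean_height_male: float = 1.67
    height_sigma_log: float = 0.04
    beverage_sodium_mg_per_kcal: float = 0.20
    snack_sodium_mg_per_kcal: float = 1.50
    kcal_per_beverage_serving: float = 150.0
    #: plausibility bound emulating standard energy-intake cleaning of
    #: food-frequency data (the raw log-normal tail would otherwise report
    #: physiologically impossible daily snack energy)
    snack_kcal_cap: float = 3500.0
    bmi_intake_rank_corr: float = 0.0
    obesity_cutoff: float = 30.0

    def validate(self) -> None:
        positive = {
            "mean_beverage_kcal": self.mean_beverage_kcal,
            "mean_snack_kcal": self.mean_snack_kcal,
            "mean_weight_kg": self.mean_weight_kg,
            "mean_bmi": self.mean_bmi,
            "weighted_population": self.weighted_population,
            "intake_share_of_energy": self.intake_share_of_energy,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not 0 <= self.obesity_prevalence < 1:
            raise ValueError(
                f"obesity_prevalence must be in [0, 1), got {self.obesity_prevalence!r}"
            )
        if not 0 < self.intake_share_of_energy < 1:
            raise ValueError("intake_share_of_energy must be in (0, 1)")
        if not -1 < self.bmi_intake_rank_corr < 1:
            raise ValueError("bmi_intake_rank_corr must be in (-1, 1)")
        if abs(sum(self.ses_probs) - 1.0) > 1e-9:
            raise ValueError("ses_probs must sum to 1")


@dataclass(frozen=True)
class ExclusionReport:
    """Bookkeeping for plausibility exclusions applied to a cohort."""

    n_input: int
    n_excluded_by_rule: dict[str, int]
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_retained + sum(self.n_excluded_by_rule.values()):
            raise ValueError("exclusion counts do not add up to the input size")


def _systematic_uniforms(rng: np.random.Generator, n: int) -> np.ndarray:
    """One uniform per 1/n stratum, in random order (variance-reduced)."""
    u = (rng.permutation(n) + rng.random(n)) / n
    return np.clip(u, 1e-12, 1 - 1e-12)


def _solve_bmi_lognormal(mean_bmi: float, prevalence: float, cutoff: float) -> tuple[float, float]:
    """Solve log-normal (mu, sigma) hitting the BMI mean and P(BMI >= cutoff).

    With BMI ~ LogNormal(mu, sigma): exp(mu + sigma^2/2) = mean and
    (ln cutoff - mu)/sigma = z where Phi(z) = 1 - prevalence.  Eliminating mu
    gives sigma^2/2 - z*sigma + ln(cutoff/mean) = 0; the smaller positive root
    is taken (the unimodal, survey-like dispersion).
    """
    log_ratio = np.log(cutoff / mean_bmi)
    if prevalence == 0.0:
        if log_ratio <= 0:
            raise CalibrationError(
                f"obesity_prevalence=0 infeasible with mean BMI {mean_bmi} >= cutoff {cutoff}"
            )
        sigma = min(0.2, log_ratio / 8.0)  # puts the cutoff >= 8 sd into the tail
        return np.log(mean_bmi) - sigma**2 / 2.0, sigma
    z = stats.norm.ppf(1.0 - prevalence)
    disc = z * z - 2.0 * log_ratio
    if disc < 0:
        raise CalibrationError(
            "BMI targets infeasible: no log-normal attains mean "
            f"{mean_bmi} with P(BMI>={cutoff})={prevalence} "
            f"(need z^2 >= 2*ln(cutoff/mean); z={z:.4f}, ln ratio={log_ratio:.4f})"
        )
    roots = [z - np.sqrt(disc), z + np.sqrt(disc)]
    sigma = min((r for r in roots if r > 0), default=None)
    if sigma is None:
        raise CalibrationError(
            f"BMI targets infeasible: solved dispersion non-positive (roots {roots})"
        )
    mu = np.log(cutoff) - z * sigma
    return mu, sigma


def _calibrated_lognormal(
    uniforms: np.ndarray,
    sigma: float,
    multipliers: np.ndarray,
    target_mean: float,
    weights: np.ndarray,
    cap: float | None = None,
    n_iter: int = 8,
) -> np.ndarray:
    """Right-skewed draws with a weighted mean ratio-calibrated to target."""
    x = np.exp(sigma * stats.norm.ppf(uniforms) - sigma**2 / 2.0) * multipliers
    for _ in range(n_iter):
        x = x * (target_mean / np.average(x, weights=weights))
        if cap is not None:
            np.minimum(x, cap, out=x)
    return x


def generate_cohort(
    n: int,
    seed: int,
    targets: CalibrationTargets | None = None,
) -> pd.DataFrame:
    """Generate a seeded synthetic cohort hitting the calibration targets.

    Parameters
    ----------
    n
        Cohort size (>= 100).
    seed
        Master seed; all randomness derives from it (same seed, same cohort).
    targets
        Calibration targets; defaults to the 2016 survey analytic sample.

    Returns
    -------
    pandas.DataFrame
        One row per individual with columns :data:`COHORT_COLUMNS`.

    Raises
    ------
    CalibrationError
        If the targets are jointly infeasible, or the realized cohort misses
        a target beyond tolerance (means 1%, prevalence 0.5 pp, weight total
        0.1%).
    """
    if n < 100:
        raise ValueError(f"n must be >= 100, got {n}")
    targets = targets if targets is not None else CalibrationTargets()
    targets.validate()

    streams = np.random.SeedSequence(seed).spawn(8)
    (r_demo, r_bmi, r_height, r_sw, r_bev, r_snack, r_other, r_corr) = (
        np.random.default_rng(s) for s in streams
    )

    # --- demographics and survey design ---------------------------------
    age = r_demo.integers(20, 60, size=n)
    sex = np.where(r_demo.random(n) < targets.female_fraction, "female", "male")
    ses = r_demo.choice(np.array(SES_LEVELS), size=n, p=list(targets.ses_probs))
    n_strata = max(2, n // 120)
    stratum_id = np.arange(n) % n_strata
    psu_id = stratum_id * 2 + (np.arange(n) // n_strata) % 2  # 2 PSUs per stratum

    # --- BMI: closed-form log-normal truncated at the implausible bound --
    mu, sigma = _solve_bmi_lognormal(
        targets.mean_bmi, targets.obesity_prevalence, targets.obesity_cutoff
    )
    u_bmi = _systematic_uniforms(r_bmi, n)
    upper = stats.norm.cdf((np.log(BMI_IMPLAUSIBLE) - mu) / sigma)
    lower = stats.norm.cdf((np.log(BMI_PLAUSIBLE_MIN) - mu) / sigma)
    lower = min(lower, 0.5 * upper)  # keep the window open for degenerate targets
    bmi = np.exp(mu + sigma * stats.norm.ppf(lower + u_bmi * (upper - lower)))

    # --- heights and body weight ----------------------------------------
    u_h = _systematic_uniforms(r_height, n)
    mean_h = np.where(sex == "female", targets.mean_height_female, targets.mean_height_male)
    height = np.exp(
        np.log(mean_h)
        - targets.height_sigma_log**2 / 2.0
        + targets.height_sigma_log * stats.norm.ppf(u_h)
    )
    weight = bmi * height**2

    # --- survey weights: lognormal baseline raked to margins -------------
    sw = r_sw.lognormal(0.0, targets.survey_weight_sigma_log, size=n)
    obese = bmi >= targets.obesity_cutoff
    if obese.any() and (~obese).any():
        # rake the obesity margin so the weighted prevalence equals the
        # (variance-reduced) unweighted proportion
        p_unw = obese.mean()
        sw[obese] *= p_unw * sw.sum() / sw[obese].sum()
        sw[~obese] *= (1.0 - p_unw) * sw.sum() / sw[~obese].sum()
    sw *= targets.weighted_population / sw.sum()

    # one multiplicative height adjustment pins the weighted mean weight
    height *= np.sqrt(targets.mean_weight_kg / np.average(weight, weights=sw))
    weight = bmi * height**2

    # --- labelled-product intakes ----------------------------------------
    mult = targets.multipliers.vector(age, sex, ses)
    rho = targets.bmi_intake_rank_corr
    if rho != 0.0:
        z_bmi = stats.norm.ppf(lower + u_bmi * (upper - lower))
        u_bev = stats.norm.cdf(rho * z_bmi + np.sqrt(1 - rho * rho) * r_corr.standard_normal(n))
        u_snk = stats.norm.cdf(rho * z_bmi + np.sqrt(1 - rho * rho) * r_corr.standard_normal(n))
        u_bev = np.clip(u_bev, 1e-12, 1 - 1e-12)
        u_snk = np.clip(u_snk, 1e-12, 1 - 1e-12)
    else:
        u_bev = _systematic_uniforms(r_bev, n)
        u_snk = _systematic_uniforms(r_snack, n)

    serving_cap = MAX_BEVERAGE_SERVINGS * targets.kcal_per_beverage_serving
    beverage_kcal = _calibrated_lognormal(
        u_bev, targets.intake_sigma_log, mult, targets.mean_beverage_kcal, sw, cap=serving_cap
    )
    snack_kcal = _calibrated_lognormal(
        u_snk, targets.intake_sigma_log, mult, targets.mean_snack_kcal, sw,
        cap=targets.snack_kcal_cap,
    )

    # energy from everything else, sized so labelled products are the
    # target share of total energy on average
    other_target = (targets.mean_beverage_kcal + targets.mean_snack_kcal) * (
        1.0 / targets.intake_share_of_energy - 1.0
    )
    other_kcal = _calibrated_lognormal(
        _systematic_uniforms(r_other, n),
        targets.other_energy_sigma_log,
        np.ones(n),
        other_target,
        sw,
    )
    total_energy = beverage_kcal + snack_kcal + other_kcal

    cohort = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "age": age,
            "sex": sex,
            "ses": ses,
            "height": height,
            "weight": weight,
            "bmi": bmi,
            "beverage_kcal": beverage_kcal,
            "snack_kcal": snack_kcal,
            "total_energy_kcal": total_energy,
            "beverage_sodium_mg": beverage_kcal * targets.beverage_sodium_mg_per_kcal,
            "snack_sodium_mg": snack_kcal * targets.snack_sodium_mg_per_kcal,
            "beverage_servings": beverage_kcal / targets.kcal_per_beverage_serving,
            "survey_weight": sw,
            "stratum_id": stratum_id,
            "psu_id": psu_id,
        }
    )
    _check_calibration(cohort, targets)
    return cohort


def _check_calibration(cohort: pd.DataFrame, targets: CalibrationTargets) -> None:
    sw = cohort["survey_weight"].to_numpy()
    checks = {
        "beverage_kcal": (np.average(cohort["beverage_kcal"], weights=sw), targets.mean_beverage_kcal),
        "snack_kcal": (np.average(cohort["snack_kcal"], weights=sw), targets.mean_snack_kcal),
        "weight": (np.average(cohort["weight"], weights=sw), targets.mean_weight_kg),
        "bmi": (np.average(cohort["bmi"], weights=sw), targets.mean_bmi),
    }
    for name, (got, want) in checks.items():
        if abs(got - want) > 0.01 * want:
            raise CalibrationError(
                f"calibration failure: weighted mean {name} {got:.3f} vs target {want:.3f}"
            )
    prev = np.average(cohort["bmi"] >= targets.obesity_cutoff, weights=sw)
    if abs(prev - targets.obesity_prevalence) > 0.005:
        raise CalibrationError(
            f"calibration failure: weighted obesity prevalence {prev:.4f} "
            f"vs target {targets.obesity_prevalence:.4f}"
        )
    if abs(sw.sum() - targets.weighted_population) > 1e-3 * targets.weighted_population:
        raise CalibrationError("calibration failure: survey weights do not sum to the target")


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply plausibility exclusions, tagging each dropped record with a rule.

    Rules (first match wins): missing or non-positive weight/height;
    implausible BMI (>= 60 kg/m^2); extreme beverage intake
    (> 16 servings/day).  Pregnant/lactating status is carried as a report
    category but synthetic cohorts never generate such records.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    w = cohort["weight"]
    h = cohort["height"]
    masks = {
        "missing_weight_height": w.isna() | h.isna() | (w <= 0) | (h <= 0),
        "bmi_ge_60": cohort["bmi"] >= BMI_IMPLAUSIBLE,
        "servings_gt_16": cohort["beverage_servings"] > MAX_BEVERAGE_SERVINGS,
        "pregnant_lactating": pd.Series(False, index=cohort.index),
    }
    counts: dict[str, int] = {}
    already = pd.Series(False, index=cohort.index)
    for rule in EXCLUSION_RULES:
        hit = masks[rule] & ~already
        counts[rule] = int(hit.sum())
        already |= hit
    retained = cohort.loc[~already].reset_index(drop=True)
    if len(retained) == 0:
        raise ValueError("all records excluded; downstream stages require >= 1 record")
    report = ExclusionReport(
        n_input=len(cohort), n_excluded_by_rule=counts, n_retained=len(retained)
    )
    return retained, report


def exclusion_report_dict(report: ExclusionReport) -> dict:
    """JSON-serializable form of an :class:`ExclusionReport`."""
    return dataclasses.asdict(report)
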