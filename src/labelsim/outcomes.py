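"""Survey-weighted population outcomes: prevalence, cases, subgroups.

Estimation is design-based: point estimates are Horvitz-Thompson style
weighted means, and confidence intervals come from a stratified cluster
bootstrap that resamples primary sampling units (PSUs) within strata,
falling back to a record-level bootstrap when a stratum has a single PSU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hall import Trajectory

__all__ = [
    "PrevalenceResult",
    "bootstrap_weighted_mean",
    "cases_averted",
    "prevalence_trajectory",
    "stratified_changes",
    "weighted_prevalence",
]

OBESITY_CUTOFF = 30.0  # kg/m^2


@dataclass(frozen=True)
class PrevalenceResult:
    """Weighted prevalence with a design-based confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    n_effective: int
    year: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.estimate <= self.ci_high <= 1.0):
            raise ValueError(
                f"invalid prevalence result: {self.ci_low}, {self.estimate}, {self.ci_high}"
            )


def _psu_bootstrap_means(
    cohort: pd.DataFrame,
    values: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bootstrap replicates of the weighted mean, resampling PSUs in strata."""
    w = cohort["survey_weight"].to_numpy(float)
    df = pd.DataFrame(
        {
            "stratum": cohort["stratum_id"].to_numpy(),
            "psu": cohort["psu_id"].to_numpy(),
            "num": w * values,
            "den": w,
        }
    )
    psu = df.groupby(["stratum", "psu"], sort=True)[["num", "den"]].sum()
    sizes = psu.groupby(level="stratum").size()
    if (sizes < 2).any():
        warnings.warn(
            "stratum with a single PSU; falling back to record-level bootstrap",
            stacklevel=3,
        )
        idx = rng.integers(0, len(values), size=(n_boot, len(values)))
        return (w[idx] * values[idx]).sum(axis=1) / w[idx].sum(axis=1)
    num = np.zeros(n_boot)
    den = np.zeros(n_boot)
    psu_num = psu["num"].to_numpy()
    psu_den = psu["den"].to_numpy()
    start = 0
    for m in sizes.to_numpy():
        pick = start + rng.integers(0, m, size=(n_boot, m))
        num += psu_num[pick].sum(axis=1)
        den += psu_den[pick].sum(axis=1)
        start += m
    return num / den


def bootstrap_weighted_mean(
    cohort: pd.DataFrame,
    values: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Weighted mean with a stratified-cluster-bootstrap percentile CI."""
    values = np.asarray(values, float)
    w = cohort["survey_weight"].to_numpy(float)
    est = float(np.average(values, weights=w))
    if n_boot <= 0:
        return est, est, est
    rng = np.random.default_rng(seed)
    reps = _psu_bootstrap_means(cohort, values, n_boot, rng)
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return est, min(float(lo), est), max(float(hi), est)


def weighted_prevalence(
    cohort: pd.DataFrame,
    bmi_values: np.ndarray | None = None,
    cutoff: float = OBESITY_CUTOFF,
    n_boot: int = 1000,
    seed: int = 0,
    year: int = 0,
) -> PrevalenceResult:
    """Survey-weighted obesity prevalence P(BMI >= cutoff) with CI.

    ``bmi_values`` defaults to the cohort's baseline BMI column; pass a
    simulated BMI snapshot to evaluate a post-intervention year.
    """
    if bmi_values is None:
        bmi_values = cohort["bmi"].to_numpy(float)
    bmi_values = np.asarray(bmi_values, float)
    if len(bmi_values) != len(cohort):
        raise ValueError("bmi_values must align one-to-one with the cohort")
    ind = (bmi_values >= cutoff).astype(float)
    est, lo, hi = bootstrap_weighted_mean(cohort, ind, n_boot=n_boot, seed=seed)
    return PrevalenceResult(
        estimate=est,
        ci_low=max(0.0, lo),
        ci_high=min(1.0, hi),
        n_effective=len(cohort),
        year=year,
    )


def _aligned_bmi(cohort: pd.DataFrame, trajectory: Trajectory) -> np.ndarray:
    """Trajectory BMI matrix reordered to cohort row order."""
    pos = pd.Series(np.arange(len(trajectory.person_id)), index=trajectory.person_id)
    missing = cohort.loc[~cohort["person_id"].isin(pos.index), "person_id"]
    if len(missing):
        raise ValueError(f"missing trajectory for person_id(s) {missing.head(10).tolist()}")
    return trajectory.bmi[pos.loc[cohort["person_id"]].to_numpy()]


def prevalence_trajectory(
    cohort: pd.DataFrame,
    trajectory: Trajectory,
    cutoff: float = OBESITY_CUTOFF,
) -> pd.DataFrame:
    """Yearly weighted prevalence and absolute change in percentage points.

    ``change_pp`` is 100*(prevalence(t) − prevalence(0)); negative values
    mean the intervention lowered prevalence.
    """
    bmi = _aligned_bmi(cohort, trajectory)
    w = cohort["survey_weight"].to_numpy(float)
    prev = (np.where(bmi >= cutoff, 1.0, 0.0) * w[:, None]).sum(axis=0) / w.sum()
    return pd.DataFrame(
        {
            "year": trajectory.years,
            "prevalence": prev,
            "change_pp": 100.0 * (prev - prev[0]),
        }
    )


def cases_averted(prev_change_pp: float, baseline_cases: float) -> int:
    """Obesity cases averted (thousand persons) from a prevalence change.

    ``prev_change_pp`` is the absolute prevalence reduction in percentage
    points; ``baseline_cases`` the adults living with obesity (thousands)
    under the steady-state assumption.  Linear in both arguments, rounded
    to integer thousands for reporting.
    """
    if not baseline_cases > 0:
        raise ValueError(f"baseline_cases must be > 0, got {baseline_cases}")
    return int(round(baseline_cases * prev_change_pp / 100.0))


_STRATA = {
    "age_band": lambda c: np.where(c["age"] < 40, "20-39", "40-59"),
    "sex": lambda c: c["sex"].to_numpy(),
    "ses": lambda c: c["ses"].to_numpy(),
}


def stratified_changes(
    cohort: pd.DataFrame,
    trajectory: Trajectory,
    cutoff: float = OBESITY_CUTOFF,
) -> pd.DataFrame:
    """Relative (%) year-5 prevalence change by age band, sex and SES.

    Relative change = 100 * (final-year change in stratum prevalence) /
    (stratum baseline prevalence).  Empty strata are omitted with a
    warning; strata with zero baseline prevalence are reported as NaN.
    """
    bmi = _aligned_bmi(cohort, trajectory)
    w = cohort["survey_weight"].to_numpy(float)
    ind0 = bmi[:, 0] >= cutoff
    ind5 = bmi[:, -1] >= cutoff
    rows = []
    for var, fn in _STRATA.items():
        labels = fn(cohort)
        for level in pd.unique(labels):
            mask = labels == level
            if not mask.any():
                warnings.warn(f"empty stratum {var}={level}; omitted")
                continue
            wm = w[mask]
            p0 = float(np.average(ind0[mask], weights=wm))
            p5 = float(np.average(ind5[mask], weights=wm))
            rel = 100.0 * (p5 - p0) / p0 if p0 > 0 else float("nan")
            rows.append(
                {
                    "stratum": var,
                    "level": level,
                    "baseline_prevalence": p0,
                    "change_pp": 100.0 * (p5 - p0),
                    "relative_change_pct": rel,
                }
            )
    return pd.DataFrame(rows)
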