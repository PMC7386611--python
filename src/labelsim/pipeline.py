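"""End-to-end orchestration: generate -> exclude -> scenario -> simulate ->
aggregate -> cost, producing the report tables.

Every run is driven by a :class:`~labelsim.config.RunConfig`; per-stage RNG
streams are spawned from the single master seed, so e.g. changing the
bootstrap replicate count never perturbs cohort generation.  Reports carry
the config hash and are byte-reproducible for a fixed configuration.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cohort import apply_exclusions, generate_cohort
from .config import RunConfig
from .costs import benefit_cost_ratio, project_costs, savings
from .hall import Trajectory, init_state, simulate
from .outcomes import (
    bootstrap_weighted_mean,
    cases_averted,
    prevalence_trajectory,
    stratified_changes,
)
from .scenarios import Scenario, builtin_scenarios, get_scenario, scenario_deltas

__all__ = ["ReportBundle", "run_pipeline", "simulate_sources"]

log = logging.getLogger("labelsim")

#: Delta-column pairs defining the beverage/snack source decomposition.
SOURCES = {
    "total": ("d_total_kcal", "d_sodium_mg"),
    "beverages": ("d_beverage_kcal", "d_beverage_sodium_mg"),
    "snacks": ("d_snack_kcal", "d_snack_sodium_mg"),
}


@dataclass
class ReportBundle:
    """The pipeline's report surfaces plus run metadata."""

    table1: pd.DataFrame  # baseline intake and expected kcal change
    table2: pd.DataFrame  # weight / BMI / prevalence / cases
    table3: pd.DataFrame  # baseline costs and cost change
    fig3: pd.DataFrame  # subgroup relative prevalence changes
    fig4: pd.DataFrame  # scenario range of cases averted
    metadata: dict = field(default_factory=dict)


def simulate_sources(
    cohort: pd.DataFrame,
    state,
    scenario: Scenario,
    config: RunConfig,
    sources: tuple[str, ...] = ("total", "beverages", "snacks"),
) -> dict[str, Trajectory]:
    """Simulate the scenario with the per-source decomposition.

    The beverage-only (snack-only) run zeroes the other category's energy
    and sodium deltas, matching the additive per-source presentation of the
    report tables.
    """
    deltas = scenario_deltas(cohort, scenario)
    out: dict[str, Trajectory] = {}
    for source in sources:
        kcal_col, na_col = SOURCES[source]
        out[source] = simulate(
            state,
            config.hall,
            (deltas[kcal_col].to_numpy(), deltas[na_col].to_numpy()),
            horizon_days=config.horizon_days,
            dt_days=config.dt_days,
        )
    return out


def _wmean_ci(cohort, values, n_boot, seed):
    est, lo, hi = bootstrap_weighted_mean(cohort, values, n_boot=n_boot, seed=seed)
    return est, lo, hi


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-12s %6.2f s", name, t1 - t0)
    return t1


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run every stage under the configured seed and return the reports."""
    config.validate()
    master = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in master.spawn(4)]
    cohort_seed, boot_seed_t1, boot_seed_t2, _ = seeds

    t0 = time.perf_counter()
    cohort = generate_cohort(config.n, cohort_seed, config.targets)
    cohort, excl = apply_exclusions(cohort)
    log.info("cohort: %d generated, %d retained", excl.n_input, excl.n_retained)
    t0 = _stage("generate", t0)

    scenario = get_scenario(config.scenario)
    deltas = scenario_deltas(cohort, scenario)
    state = init_state(cohort, config.hall, pal=config.pal, ecf_fraction=config.ecf_fraction)
    trajs = simulate_sources(cohort, state, scenario, config)
    t0 = _stage("simulate", t0)

    # --- Table 1: baseline intake and expected change -------------------
    w = cohort["survey_weight"].to_numpy(float)
    total_energy = float(np.average(cohort["total_energy_kcal"], weights=w))
    rows1 = []
    for label, base_col, d_col in (
        ("beverages", "beverage_kcal", "d_beverage_kcal"),
        ("snacks", "snack_kcal", "d_snack_kcal"),
        ("total", None, "d_total_kcal"),
    ):
        base = (
            cohort["beverage_kcal"] + cohort["snack_kcal"]
            if base_col is None
            else cohort[base_col]
        ).to_numpy(float)
        b, b_lo, b_hi = _wmean_ci(cohort, base, config.n_boot, boot_seed_t1)
        d, d_lo, d_hi = _wmean_ci(
            cohort, deltas[d_col].to_numpy(), config.n_boot, boot_seed_t1
        )
        rows1.append(
            {
                "category": label,
                "baseline_kcal": b,
                "baseline_ci_low": b_lo,
                "baseline_ci_high": b_hi,
                "pct_of_total_energy": 100.0 * b / total_energy,
                "change_kcal": d,
                "change_ci_low": d_lo,
                "change_ci_high": d_hi,
            }
        )
    table1 = pd.DataFrame(rows1)
    t0 = _stage("table1", t0)

    # --- Table 2: weight, BMI, prevalence, cases -------------------------
    cutoff = config.cutoff
    ind0 = (trajs["total"].bmi[:, 0] >= cutoff).astype(float)
    base_cells = {
        "body_weight_kg": cohort["weight"].to_numpy(float),
        "bmi_kg_m2": cohort["bmi"].to_numpy(float),
        "obesity_prevalence_pp": 100.0 * ind0,
    }
    change_cells = {}
    for source, traj in trajs.items():
        ind5 = (traj.bmi[:, -1] >= cutoff).astype(float)
        change_cells[source] = {
            "body_weight_kg": traj.delta_weight[:, -1],
            "bmi_kg_m2": traj.delta_bmi[:, -1],
            "obesity_prevalence_pp": 100.0 * (ind5 - ind0),
        }
    rows2 = []
    pp_change = {}
    for output, base_vals in base_cells.items():
        b, b_lo, b_hi = _wmean_ci(cohort, base_vals, config.n_boot, boot_seed_t2)
        row = {
            "output": output,
            "baseline": b,
            "baseline_ci_low": b_lo,
            "baseline_ci_high": b_hi,
        }
        for source in ("beverages", "snacks", "total"):
            d, d_lo, d_hi = _wmean_ci(
                cohort, change_cells[source][output], config.n_boot, boot_seed_t2
            )
            row[f"change_{source}"] = d
            row[f"change_{source}_ci_low"] = d_lo
            row[f"change_{source}_ci_high"] = d_hi
            if output == "obesity_prevalence_pp":
                pp_change[source] = d
        rows2.append(row)
    cases_row = {
        "output": "obesity_cases_thousand",
        "baseline": config.baseline_cases_thousands,
        "baseline_ci_low": float("nan"),
        "baseline_ci_high": float("nan"),
    }
    for source in ("beverages", "snacks", "total"):
        cases_row[f"change_{source}"] = cases_averted(
            -pp_change[source], config.baseline_cases_thousands
        )
        cases_row[f"change_{source}_ci_low"] = float("nan")
        cases_row[f"change_{source}_ci_high"] = float("nan")
    rows2.append(cases_row)
    table2 = pd.DataFrame(rows2)
    t0 = _stage("table2", t0)

    # --- Fig 3: subgroup relative changes --------------------------------
    fig3 = stratified_changes(cohort, trajs["total"], cutoff=cutoff)
    t0 = _stage("fig3", t0)

    # --- Fig 4: scenario range of cases averted --------------------------
    rows4 = []
    for sc in builtin_scenarios():
        sc_trajs = (
            {k: trajs[k] for k in ("beverages", "snacks")}
            if sc.name == scenario.name
            else simulate_sources(cohort, state, sc, config, sources=("beverages", "snacks"))
        )
        row = {"scenario": sc.name}
        for source in ("beverages", "snacks"):
            path = prevalence_trajectory(cohort, sc_trajs[source], cutoff=cutoff)
            row[f"cases_averted_{source}"] = cases_averted(
                -float(path["change_pp"].iloc[-1]), config.baseline_cases_thousands
            )
        rows4.append(row)
    fig4 = pd.DataFrame(rows4)
    t0 = _stage("fig4", t0)

    # --- Table 3: costs ---------------------------------------------------
    stream = project_costs(config.cost)
    path = prevalence_trajectory(cohort, trajs["total"], cutoff=cutoff)
    reductions_pp = (-path["change_pp"].to_numpy())[1:]  # years 1..horizon
    sav = savings(reductions_pp, stream)
    table3 = pd.DataFrame(
        {
            "cost_output": ["direct_musd", "indirect_musd", "total_musd"],
            "baseline_cost": [
                stream.totals["direct"],
                stream.totals["indirect"],
                stream.totals["total"],
            ],
            "change": [-sav.direct, -sav.indirect, -sav.total],
        }
    )
    bcr = benefit_cost_ratio(sav.total, config.cost.implementation_cost_usd)
    _stage("table3", t0)

    metadata = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "scenario": scenario.name,
        "n_generated": excl.n_input,
        "n_retained": excl.n_retained,
        "n_excluded_by_rule": excl.n_excluded_by_rule,
        "benefit_cost_ratio": round(bcr, 1),
        "labelsim_version": __version__,
    }
    return ReportBundle(
        table1=table1, table2=table2, table3=table3, fig3=fig3, fig4=fig4, metadata=metadata
    )
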