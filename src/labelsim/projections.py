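"""Adult population projections and steady-state obesity case counts.

Cases averted need the number of adults (20-59) living with obesity over
the policy horizon.  Under the steady-state assumption that prevalence
moves only through the label intervention, baseline cases are the steady
prevalence applied to the projected adult population.  A synthetic
projection series shaped like the official national projections for
2019-2023 is bundled; supply the official series as CSV
(columns: year, adults_20_59_thousand) for production use.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SYNTHETIC_ADULT_POPULATION_20_59",
    "baseline_obesity_cases",
    "load_projection_csv",
]

#: Synthetic stand-in projection of Mexican adults aged 20-59 (thousands),
#: constructed so its 2019-2023 mean times the 37.8% steady obesity
#: prevalence reproduces the 26,174 thousand baseline case count.
SYNTHETIC_ADULT_POPULATION_20_59: dict[int, float] = {
    2019: 68_400.0,
    2020: 68_830.0,
    2021: 69_245.0,
    2022: 69_655.0,
    2023: 70_085.0,
}


def baseline_obesity_cases(
    projection: Mapping[int, float] | None = None,
    steady_prevalence: float = 0.378,
) -> float:
    """Adults with obesity (thousands): steady prevalence x mean population."""
    if projection is None:
        projection = SYNTHETIC_ADULT_POPULATION_20_59
    if not 0 < steady_prevalence < 1:
        raise ValueError(f"steady_prevalence must be in (0, 1), got {steady_prevalence}")
    return steady_prevalence * float(np.mean(list(projection.values())))


def load_projection_csv(path) -> dict[int, float]:
    """Read a projection CSV with columns year, adults_20_59_thousand."""
    df = pd.read_csv(path)
    missing = {"year", "adults_20_59_thousand"} - set(df.columns)
    if missing:
        raise ValueError(f"projection CSV missing column(s): {sorted(missing)}")
    return {int(r.year): float(r.adults_20_59_thousand) for r in df.itertuples()}
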