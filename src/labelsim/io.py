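"""Cohort CSV round-trips and report writing.

The cohort CSV contract is one row per individual with exactly the columns
of :data:`labelsim.cohort.COHORT_COLUMNS` (UTF-8, "." decimal).  Reading
validates every row and reports offending file line numbers (header is
line 1).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS, SES_LEVELS, SEX_LEVELS

__all__ = ["CohortFormatError", "read_cohort", "write_cohort", "write_reports"]

_NUMERIC = (
    "age",
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
)
_POSITIVE = ("height", "weight", "survey_weight")


class CohortFormatError(ValueError):
    """A cohort CSV violates the documented column/row contract."""


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort frame to CSV at full float precision."""
    cohort.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises
    ------
    CohortFormatError
        Naming any missing required column, or listing the file line
        numbers of malformed rows (non-numeric fields, non-positive
        height/weight/survey weight, unknown sex/SES levels, BMI
        inconsistent with weight/height).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing required column(s): {', '.join(missing)}")
    problems: list[str] = []
    for col in _NUMERIC:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        for idx in df.index[bad][:5]:
            problems.append(f"line {idx + 2}: non-numeric {col}={df.at[idx, col]!r}")
        df[col] = vals
    for col in _POSITIVE:
        bad = df[col].isna() | (df[col] <= 0)
        for idx in df.index[bad][:5]:
            problems.append(f"line {idx + 2}: {col} must be strictly positive")
    bad_sex = ~df["sex"].isin(SEX_LEVELS)
    for idx in df.index[bad_sex][:5]:
        problems.append(f"line {idx + 2}: unknown sex {df.at[idx, 'sex']!r}")
    bad_ses = ~df["ses"].isin(SES_LEVELS)
    for idx in df.index[bad_ses][:5]:
        problems.append(f"line {idx + 2}: unknown ses {df.at[idx, 'ses']!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        implied = df["weight"] / df["height"] ** 2
    bad_bmi = (np.abs(implied - df["bmi"]) > 1e-6 * np.maximum(1.0, np.abs(df["bmi"]))) & (
        df["height"] > 0
    )
    for idx in df.index[bad_bmi][:5]:
        problems.append(
            f"line {idx + 2}: bmi {df.at[idx, 'bmi']:.4f} inconsistent with weight/height^2"
        )
    if problems:
        raise CohortFormatError("malformed cohort rows:\n  " + "\n  ".join(problems))
    return df


def write_reports(bundle, outdir) -> dict[str, Path]:
    """Write every report table as CSV plus run metadata JSON.

    Each table file starts with a ``# config_hash=`` comment line so any
    artifact can be traced to the configuration that produced it; rerunning
    with the same configuration reproduces the files byte-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hash_line = f"# config_hash={bundle.metadata['config_hash']}\n"
    written: dict[str, Path] = {}
    for name in ("table1", "table2", "table3", "fig3", "fig4"):
        path = outdir / f"{name}.csv"
        frame = getattr(bundle, name)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(hash_line)
            frame.to_csv(fh, index=False, float_format="%.10g")
        written[name] = path
    meta_path = outdir / "run_metadata.json"
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(bundle.metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["metadata"] = meta_path
    return written
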