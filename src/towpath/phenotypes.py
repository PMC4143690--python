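"""Baseline selection, derived blood-pressure phenotypes, and descriptives.

Two composite phenotypes are derived from systolic and diastolic pressure:
mean arterial pressure MAP = (2/3) DBP + (1/3) SBP, and the pulse gap
SBP - DBP (pulse pressure). Rows with SBP < DBP are physically implausible;
they are flagged and excluded from the derived columns rather than silently
dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CONTINUOUS_VARS = ["SBP", "DBP", "MAP", "pulse_gap", "age"]
BINARY_VARS = ["hypertension", "sex", "medication_use", "smoking"]


def select_baseline(cohort: pd.DataFrame, require_genotyped: bool = True) -> pd.DataFrame:
    """One row per individual at the earliest visit, optionally restricted to
    individuals with genotype data."""
    if cohort.empty:
        raise ValueError("cohort is empty")
    if cohort.duplicated(subset=["individual_id", "visit"]).any():
        dup = cohort.loc[
            cohort.duplicated(subset=["individual_id", "visit"]), "individual_id"
        ]
        raise ValueError(f"duplicate (individual, visit) keys: {sorted(set(dup))[:5]}")
    n_in = cohort["individual_id"].nunique()
    baseline = (
        cohort.sort_values(["individual_id", "visit"], kind="stable")
        .groupby("individual_id", as_index=False, sort=True)
        .first()
    )
    if require_genotyped:
        baseline = baseline[baseline["genotyped"] == 1].reset_index(drop=True)
    log.info(
        "baseline selection: %d individuals in, %d retained (require_genotyped=%s)",
        n_in, len(baseline), require_genotyped,
    )
    return baseline


def derive_phenotypes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add MAP and pulse_gap columns; flag implausible or missing BP rows.

    MAP = (2/3) DBP + (1/3) SBP exactly; pulse_gap = SBP - DBP exactly.
    Rows with missing SBP/DBP or SBP < DBP get ``bp_flagged = 1`` and NaN in
    the derived columns.
    """
    out = cohort.copy()
    sbp = out["SBP"].to_numpy(dtype=float)
    dbp = out["DBP"].to_numpy(dtype=float)
    bad = ~np.isfinite(sbp) | ~np.isfinite(dbp) | (sbp < dbp) | (sbp <= 0) | (dbp <= 0)
    if bad.any():
        log.warning("%d rows flagged (missing or implausible SBP/DBP)", int(bad.sum()))
    map_ = (2.0 * dbp + sbp) / 3.0  # == (2/3) DBP + (1/3) SBP, better conditioned
    gap = sbp - dbp
    map_[bad] = np.nan
    gap[bad] = np.nan
    out["MAP"] = map_
    out["pulse_gap"] = gap
    out["bp_flagged"] = bad.astype(int)
    return out


def descriptive_stats(cohort: pd.DataFrame) -> pd.DataFrame:
    """Descriptive summary of the baseline cohort.

    Continuous variables: mean and sample SD (denominator n-1); binary
    variables: n and percent of ones. Returned as a tidy table with a
    pre-formatted ``summary`` column mirroring the usual
    "mean +/- SD" / "n (%)" layout.
    """
    if cohort.empty:
        raise ValueError("cannot summarize an empty cohort")
    rows = []
    for var in CONTINUOUS_VARS:
        if var not in cohort.columns:
            continue
        vals = cohort[var].dropna()
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            {
                "variable": var, "kind": "continuous", "n": int(len(vals)),
                "mean": mean, "sd": sd, "percent": np.nan,
                "summary": f"{mean:.1f} ± {sd:.1f}",
            }
        )
    for var in BINARY_VARS:
        if var not in cohort.columns:
            continue
        vals = cohort[var].dropna()
        pct = 100.0 * float(vals.mean()) if len(vals) else np.nan
        rows.append(
            {
                "variable": var, "kind": "binary", "n": int(len(vals)),
                "mean": np.nan, "sd": np.nan, "percent": pct,
                "summary": f"{int(len(vals))} ({pct:.1f})",
            }
        )
    return pd.DataFrame(rows)


def format_descriptives(stats: pd.DataFrame) -> str:
    """Pretty-print the summary table."""
    width = max(len(v) for v in stats["variable"]) + 2
    lines = [f"{'Variable':<{width}}Summary measure"]
    for rec in stats.itertuples(index=False):
        lines.append(f"{rec.variable:<{width}}{rec.summary}")
    return "\n".join(lines)
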