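"""Cohort assembly: hypertrophy flags, category partition, prevalent-case
removal and phenotype correlation summaries.

Hypertrophy is defined within sex: a subject is flagged when a mass strictly
exceeds that sex's empirical percentile (linear-interpolation quantile,
90th by default). The three flags (global = total LVM, apical, septal)
partition the cohort into eight cells; survival modelling uses the disjoint
five-group view (control / global / isolated apical / isolated septal /
combined apical+septal without global).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

#: eight-cell category names keyed by (global, apical, septal) flags
CATEGORY_BY_FLAGS = {
    (0, 0, 0): "none",
    (1, 0, 0): "global_only",
    (0, 1, 0): "isolated_apical",
    (0, 0, 1): "isolated_septal",
    (0, 1, 1): "apical_and_septal",
    (1, 1, 0): "global_plus_apical",
    (1, 0, 1): "global_plus_septal",
    (1, 1, 1): "global_plus_both",
}

#: disjoint modelling groups derived from the eight cells
MODEL_GROUPS = ("control", "global", "isolated_apical", "isolated_septal", "combined")


def sex_specific_percentile_flag(
    table: pd.DataFrame,
    mass_column: str,
    percentile: float = 90.0,
    sex_column: str = "sex",
) -> tuple[pd.Series, dict[str, float]]:
    """Flag subjects whose mass strictly exceeds their sex's percentile.

    Returns the binary column and the per-sex threshold values (grams).
    """
    if mass_column not in table.columns:
        raise ValidationError(f"missing column {mass_column!r}")
    if table[mass_column].isna().all():
        raise ValidationError(f"column {mass_column!r} is entirely missing")
    flags = pd.Series(0, index=table.index, dtype=int)
    thresholds: dict[str, float] = {}
    for sex, grp in table.groupby(sex_column):
        vals = grp[mass_column].dropna()
        if len(vals) < 2:
            raise ValidationError(f"need >= 2 subjects with {mass_column} for sex {sex!r}")
        thr = float(np.quantile(vals.to_numpy(), percentile / 100.0, method="linear"))
        thresholds[str(sex)] = thr
        flags.loc[grp.index] = (grp[mass_column] > thr).astype(int)
    log.info("%s p%g thresholds: %s", mass_column, percentile, thresholds)
    return flags, thresholds


def add_hypertrophy_flags(
    table: pd.DataFrame, percentile: float = 90.0
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Append hyp_global / hyp_apical / hyp_septal flag columns."""
    out = table.copy()
    thresholds = {}
    for flag, col in (
        ("hyp_global", "total_mass_g"),
        ("hyp_apical", "apical_mass_g"),
        ("hyp_septal", "septal_mass_g"),
    ):
        out[flag], thresholds[flag] = sex_specific_percentile_flag(out, col, percentile)
    return out, thresholds


def assign_categories(table: pd.DataFrame) -> pd.DataFrame:
    """Map flag triples onto the eight-cell partition and the model groups.

    Appends ``category`` (8 cells, exactly one per subject) and
    ``model_group`` (control / global / isolated_apical / isolated_septal /
    combined, also a partition: any global flag wins, combined requires both
    regional flags without global).
    """
    for col in ("hyp_global", "hyp_apical", "hyp_septal"):
        if col not in table.columns:
            raise ValidationError(f"missing flag column {col!r}")
    out = table.copy()
    g = out["hyp_global"].astype(int)
    a = out["hyp_apical"].astype(int)
    s = out["hyp_septal"].astype(int)
    out["category"] = [
        CATEGORY_BY_FLAGS[(gi, ai, si)] for gi, ai, si in zip(g, a, s, strict=True)
    ]
    model = np.where(
        g == 1,
        "global",
        np.where(
            (a == 1) & (s == 1),
            "combined",
            np.where(a == 1, "isolated_apical", np.where(s == 1, "isolated_septal", "control")),
        ),
    )
    out["model_group"] = model
    return out


def remove_prevalent(
    table: pd.DataFrame,
    outcome: str,
    baseline_column: str = "baseline_date",
    follow_up_column: str = "follow_up_end_date",
) -> tuple[pd.DataFrame, list[str]]:
    """Split prevalent cases off and derive incident event/time columns.

    A subject is prevalent for ``outcome`` when the first event date precedes
    baseline. Retained subjects get ``{outcome}_event`` (0/1) and
    ``{outcome}_time_years`` (to first event, else end of follow-up).
    Idempotent: re-applying to the returned table removes nobody.
    """
    event_col = f"{outcome}_first_event_date"
    for col in (event_col, baseline_column, follow_up_column):
        if col not in table.columns:
            raise ValidationError(f"missing column {col!r}")
    event_date = pd.to_datetime(table[event_col])
    baseline = pd.to_datetime(table[baseline_column])
    bad = event_date.notna() & baseline.isna()
    if bad.any():
        ids = table.loc[bad, "subject_id"].tolist()
        raise DataError(f"event date without baseline date for subject(s): {ids}")

    prevalent = event_date.notna() & (event_date < baseline)
    prevalent_ids = table.loc[prevalent, "subject_id"].tolist()
    kept = table.loc[~prevalent].copy()

    ev = pd.to_datetime(kept[event_col])
    base = pd.to_datetime(kept[baseline_column])
    end = pd.to_datetime(kept[follow_up_column])
    has_event = ev.notna()
    stop = ev.where(has_event, end)
    kept[f"{outcome}_event"] = has_event.astype(int)
    kept[f"{outcome}_time_years"] = (stop - base).dt.days / DAYS_PER_YEAR
    return kept, prevalent_ids


def phenotype_correlations(
    table: pd.DataFrame,
    columns: tuple[str, ...] = ("apical_mass_g", "septal_mass_g", "total_mass_g"),
) -> pd.DataFrame:
    """Pairwise-complete squared Pearson correlations (r^2) among phenotypes.

    Zero-variance columns are reported as undefined (NaN row/column), never
    as 0.
    """
    sub = table[list(columns)]
    if len(sub.dropna(how="any")) < 3:
        raise ValidationError("need >= 3 complete rows for correlations")
    r = sub.corr(method="pearson", min_periods=3)
    r2 = r**2
    degenerate = [c for c in columns if sub[c].dropna().nunique() <= 1]
    for c in degenerate:
        r2.loc[c, :] = np.nan
        r2.loc[:, c] = np.nan
    for c in columns:
        if c not in degenerate:
            r2.loc[c, c] = 1.0
    return r2
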