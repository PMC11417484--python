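"""Cox proportional-hazards model families over the assembled cohort.

Three families mirror the analysis design: (1) categorical hypertrophy
groups against the no-hypertrophy control; (2) continuous masses reported
per 1 SD; (3) joint models pairing total LVM with one regional mass to test
whether regional mass carries independent signal (the septal signal is
expected to attenuate once total LVM is in the model, the apical one to
persist). Fitting is Efron-tied Newton maximisation of the partial
likelihood with Wald confidence intervals, via lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .cohort import MODEL_GROUPS
from .errors import FitDiagnosticError, ValidationError

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("sex", "age", "pulse_rate", "hypertension")
PRS_COVARIATES = ("sex", "age", "bmi", "pulse_rate", "hypertension")

#: design-matrix condition number beyond which a fit is refused
CONDITION_NUMBER_LIMIT = 1e8


@dataclass(frozen=True)
class CoxModelSpec:
    """One Cox fit: outcome, predictors of interest, adjustment covariates."""

    outcome: str
    predictors: tuple[str, ...]
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    standardize: tuple[str, ...] = ()
    categorical: dict[str, str] = field(default_factory=dict)  # column -> reference level

    def validate(self) -> None:
        overlap = set(self.predictors) & set(self.covariates)
        if overlap:
            raise ValidationError(f"predictors also listed as covariates: {sorted(overlap)}")


def standardize_per_sd(table: pd.DataFrame, column: str) -> tuple[pd.Series, float]:
    """Divide a column by its sample SD; returns (scaled column, SD)."""
    vals = table[column].astype(float)
    sd = float(vals.std(ddof=1))
    if not np.isfinite(sd) or sd == 0.0 or vals.nunique() < 2:
        raise ValidationError(f"column {column!r} has no variance to standardize")
    return vals / sd, sd


def _encode(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Numeric design columns; 'sex' and other binary objects become 0/1."""
    out = pd.DataFrame(index=table.index)
    for col in columns:
        s = table[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.dropna().unique())
            if len(levels) > 2:
                raise ValidationError(f"column {col!r} has >2 levels; dummy-code it explicitly")
            out[col] = (s == levels[-1]).astype(float)
        else:
            out[col] = s.astype(float)
    return out


def fit_cox(table: pd.DataFrame, spec: CoxModelSpec) -> pd.DataFrame:
    """Fit one Cox model and return the hazard table.

    Columns: term, hazard_ratio, ci_low, ci_high, p_value, n_events,
    n_subjects, sd_used. Complete-case within the fit; counts logged.
    """
    spec.validate()
    duration = f"{spec.outcome}_time_years"
    event = f"{spec.outcome}_event"
    for col in (duration, event):
        if col not in table.columns:
            raise ValidationError(f"missing outcome column {col!r}")

    design_cols: list[str] = []
    df = pd.DataFrame(index=table.index)
    sd_used: dict[str, float] = {}

    for col in spec.predictors:
        if col in spec.categorical:
            ref = spec.categorical[col]
            levels = [lv for lv in pd.unique(table[col].dropna()) if lv != ref]
            for lv in sorted(map(str, levels)):
                name = f"{col}[{lv}]"
                df[name] = (table[col].astype(str) == lv).astype(float)
                design_cols.append(name)
        else:
            s = table[col].astype(float)
            if col in spec.standardize:
                s, sd_used[col] = standardize_per_sd(table, col)
            df[col] = s
            design_cols.append(col)

    cov = _encode(table, spec.covariates)
    df = pd.concat([df, cov], axis=1)
    design_cols += list(cov.columns)

    df[duration] = table[duration].astype(float)
    df[event] = table[event].astype(int)
    n_before = len(df)
    df = df.dropna()
    if n_before - len(df):
        log.info("complete-case fit drops %d of %d rows", n_before - len(df), n_before)
    n_events = int(df[event].sum())
    if n_events < 1:
        raise ValidationError(f"no events for outcome {spec.outcome!r}")

    # refuse near-singular designs before handing them to the optimiser
    x = df[design_cols].to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    scale = x.std(axis=0)
    nz = scale > 0
    if nz.any():
        cond = np.linalg.cond(x[:, nz] / scale[nz])
        if cond > CONDITION_NUMBER_LIMIT:
            raise FitDiagnosticError(
                f"design condition number {cond:.3g} exceeds {CONDITION_NUMBER_LIMIT:g}"
            )

    # Newton with decreasing step sizes: the default can overshoot on data
    # with strong effects plus heavy administrative-censoring ties even when
    # the partial-likelihood MLE is finite
    cph = CoxPHFitter()
    last_exc: Exception | None = None
    for step_size in (None, 0.5, 0.25, 0.1):
        try:
            opts = {"step_size": step_size} if step_size else None
            cph.fit(df, duration_col=duration, event_col=event, fit_options=opts)
            last_exc = None
            break
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
    if last_exc is not None:
        raise FitDiagnosticError(
            f"Cox fit failed for {spec.outcome!r}: {last_exc}"
        ) from last_exc

    summary = cph.summary
    rows = []
    for term in design_cols:
        s = summary.loc[term]
        base = term.split("[")[0]
        rows.append(
            {
                "term": term,
                "hazard_ratio": float(np.exp(s["coef"])),
                "ci_low": float(np.exp(s["coef lower 95%"])),
                "ci_high": float(np.exp(s["coef upper 95%"])),
                "p_value": float(s["p"]),
                "n_events": n_events,
                "n_subjects": len(df),
                "sd_used": sd_used.get(base, np.nan),
            }
        )
    return pd.DataFrame(rows)


def hypertrophy_hazard_table(
    table: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    group_column: str = "model_group",
) -> pd.DataFrame:
    """Categorical fit of hypertrophy groups vs the no-hypertrophy control.

    Emits one row per non-control group; empty groups get n=0 rows with no
    estimate rather than distorting the fit.
    """
    if group_column not in table.columns:
        raise ValidationError(f"missing column {group_column!r}")
    counts = table[group_column].value_counts()
    # a group without events makes its dummy column singular in the partial
    # likelihood (and a tiny all-event group can diverge); such groups get an
    # n-only row instead of an estimate, dropped smallest-first on failure
    event_counts = table.groupby(group_column)[f"{outcome}_event"].sum()
    present = sorted(
        (
            g
            for g in MODEL_GROUPS
            if g != "control" and counts.get(g, 0) > 0 and event_counts.get(g, 0) > 0
        ),
        key=lambda g: -event_counts.get(g, 0),
    )
    spec = CoxModelSpec(
        outcome=outcome,
        predictors=(group_column,),
        covariates=covariates,
        categorical={group_column: "control"},
    )
    while True:
        if not present:
            raise ValidationError(f"no estimable hypertrophy group for {outcome!r}")
        sub = table[table[group_column].isin(["control", *present])]
        try:
            ht = fit_cox(sub, spec)
            break
        except FitDiagnosticError:
            dropped = present.pop()  # fewest events
            log.warning("dropping group %r (too few events to estimate)", dropped)
    ht["group"] = [t.split("[")[1].rstrip("]") if "[" in t else t for t in ht["term"]]
    ht["n_group"] = [int(counts.get(g, 0)) for g in ht["group"]]
    missing = [g for g in MODEL_GROUPS if g != "control" and g not in present]
    for g in missing:
        ht.loc[len(ht)] = {
            "term": f"{group_column}[{g}]",
            "hazard_ratio": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p_value": np.nan,
            "n_events": np.nan,
            "n_subjects": np.nan,
            "sd_used": np.nan,
            "group": g,
            "n_group": int(counts.get(g, 0)),
        }
    return ht


def per_sd_mass_model(
    table: pd.DataFrame,
    outcome: str,
    mass_column: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """HR per 1 SD of one continuous mass, adjusted for the standard covariates."""
    spec = CoxModelSpec(
        outcome=outcome,
        predictors=(mass_column,),
        covariates=covariates,
        standardize=(mass_column,),
    )
    return fit_cox(table, spec)


def joint_mass_models(
    table: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two joint fits: (LVM + apical mass) and (LVM + septal mass), per SD."""
    out = []
    for regional in ("apical_mass_g", "septal_mass_g"):
        spec = CoxModelSpec(
            outcome=outcome,
            predictors=("total_mass_g", regional),
            covariates=covariates,
            standardize=("total_mass_g", regional),
        )
        out.append(fit_cox(table, spec))
    return out[0], out[1]
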