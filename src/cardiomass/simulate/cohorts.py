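"""Simulated imaging cohorts: masses, covariates and survival outcomes.

Per-sex total/apical/septal masses are drawn from a multivariate normal with
configurable means, SDs and a shared correlation target; defaults echo a
large adult biobank imaging cohort (male LVM ~103 g, female ~71 g, septal
mass strongly and apical mass moderately correlated with total mass).
Event times are exponential given each subject's hazard
lambda_i = baseline * exp(linear predictor), so Cox coefficient recovery has
a closed-form target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ConfigurationError

MASS_COLUMNS = ("total_mass_g", "apical_mass_g", "septal_mass_g")

#: default correlation target among (total, apical, septal) mass
DEFAULT_MASS_CORR = (
    (1.00, 0.66, 0.86),
    (0.66, 1.00, 0.60),
    (0.86, 0.60, 1.00),
)


@dataclass(frozen=True)
class SimCohortSpec:
    """Generative settings for a synthetic cohort."""

    n_subjects: int = 5000
    female_fraction: float = 0.52
    # per-sex (total, apical, septal) mass means and SDs, grams
    male_mass_means: tuple[float, float, float] = (103.0, 16.0, 38.0)
    male_mass_sds: tuple[float, float, float] = (20.0, 5.0, 9.0)
    female_mass_means: tuple[float, float, float] = (71.0, 11.0, 27.0)
    female_mass_sds: tuple[float, float, float] = (15.0, 4.0, 7.0)
    mass_corr: tuple[tuple[float, float, float], ...] = DEFAULT_MASS_CORR
    age_mean: float = 64.0
    age_sd: float = 7.5
    pulse_mean: float = 69.0
    pulse_sd: float = 11.0
    hypertension_prevalence: float = 0.30
    bmi_mean: float = 27.0
    bmi_sd: float = 4.5
    baseline_date: str = "2015-06-01"
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError("female_fraction must be in [0, 1]")
        for sds in (self.male_mass_sds, self.female_mass_sds):
            if min(sds) <= 0:
                raise ConfigurationError("mass SDs must be > 0")
        corr = np.asarray(self.mass_corr, dtype=float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ConfigurationError("mass_corr must be a symmetric 3x3 matrix")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ConfigurationError("mass_corr is not positive semi-definite")
        if not 0.0 <= self.hypertension_prevalence <= 1.0:
            raise ConfigurationError("hypertension_prevalence must be in [0, 1]")


def generate_cohort(spec: SimCohortSpec) -> pd.DataFrame:
    """Draw a cohort table; deterministic under a fixed spec (incl. seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    sex = np.where(rng.random(n) < spec.female_fraction, "female", "male")

    corr = np.asarray(spec.mass_corr, dtype=float)
    # nudge onto the PSD cone before Cholesky in case of tiny asymmetry
    w, v = np.linalg.eigh(corr)
    chol = np.linalg.cholesky(v @ np.diag(np.clip(w, 1e-12, None)) @ v.T)
    z = rng.standard_normal((n, 3)) @ chol.T

    masses = np.empty((n, 3))
    for label, means, sds in (
        ("male", spec.male_mass_means, spec.male_mass_sds),
        ("female", spec.female_mass_means, spec.female_mass_sds),
    ):
        m = sex == label
        masses[m] = np.asarray(means) + z[m] * np.asarray(sds)
    masses = np.clip(masses, 0.0, None)

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "sex": sex,
            "age": np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 40.0, 85.0),
            "pulse_rate": np.clip(rng.normal(spec.pulse_mean, spec.pulse_sd, n), 35.0, 140.0),
            "hypertension": (rng.random(n) < spec.hypertension_prevalence).astype(int),
            "bmi": np.clip(rng.normal(spec.bmi_mean, spec.bmi_sd, n), 15.0, 55.0),
            "baseline_date": pd.Timestamp(spec.baseline_date)
            + pd.to_timedelta(rng.integers(0, 365, n), unit="D"),
        }
    )
    for j, col in enumerate(MASS_COLUMNS):
        df[col] = masses[:, j]
    return df


def simulate_survival(
    table: pd.DataFrame,
    coefficients: dict[str, float],
    baseline_hazard: float,
    censoring_rate: float = 0.0,
    max_follow_up_years: float = 10.0,
    seed: int = 0,
    outcome: str = "event",
) -> pd.DataFrame:
    """Append exponential event/censoring columns for one outcome.

    Subject hazard is ``baseline_hazard * exp(sum beta_j * x_j)`` per year;
    censoring is an independent exponential race plus administrative cut-off
    at ``max_follow_up_years``. Adds ``{outcome}_time_years`` and
    ``{outcome}_event`` columns.
    """
    if baseline_hazard < 0:
        raise ConfigurationError("baseline_hazard must be >= 0")
    if censoring_rate < 0:
        raise ConfigurationError("censoring_rate must be >= 0")
    missing = [c for c in coefficients if c not in table.columns]
    if missing:
        raise ConfigurationError(f"coefficient column(s) not in table: {missing}")

    rng = np.random.default_rng(seed)
    n = len(table)
    lp = np.zeros(n)
    for col, beta in coefficients.items():
        lp += beta * table[col].to_numpy(dtype=float)
    hazard = baseline_hazard * np.exp(lp)

    with np.errstate(divide="ignore"):
        t_event = np.where(hazard > 0, rng.exponential(1.0, n) / np.maximum(hazard, 1e-300), np.inf)
        t_cens = (
            rng.exponential(1.0, n) / censoring_rate if censoring_rate > 0 else np.full(n, np.inf)
        )
    t_admin = max_follow_up_years
    time = np.minimum(np.minimum(t_event, t_cens), t_admin)
    event = (t_event <= np.minimum(t_cens, t_admin)).astype(int)

    out = table.copy()
    out[f"{outcome}_time_years"] = time
    out[f"{outcome}_event"] = event
    return out


def attach_outcome_dates(
    table: pd.DataFrame,
    outcome: str,
    prevalent_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Convert simulated times into the date fields the cohort builder consumes.

    Adds ``{outcome}_first_event_date`` (NaT when no event) and
    ``follow_up_end_date``. A ``prevalent_fraction`` of subjects is rewritten
    as prevalent cases (first event 1-5 years before baseline) to exercise
    prevalent-case removal.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    base = pd.to_datetime(out["baseline_date"])
    days = pd.to_timedelta((out[f"{outcome}_time_years"] * 365.25).round(), unit="D")
    event = out[f"{outcome}_event"].astype(bool)
    out[f"{outcome}_first_event_date"] = (base + days).where(event, pd.NaT)
    out["follow_up_end_date"] = base + days
    if prevalent_fraction > 0:
        prev = rng.random(len(out)) < prevalent_fraction
        back = pd.to_timedelta(rng.integers(365, 5 * 365, len(out)), unit="D")
        col = f"{outcome}_first_event_date"
        out.loc[prev, col] = base[prev] - back[prev]
    return out


@dataclass(frozen=True)
class CategoryEffects:
    """True per-category log hazards used when simulating categorical risk."""

    global_hypertrophy: float = float(np.log(9.28))
    isolated_apical: float = float(np.log(2.69))
    isolated_septal: float = float(np.log(4.41))
    combined: float = float(np.log(5.0))

    def as_dict(self) -> dict[str, float]:
        return {
            "global": self.global_hypertrophy,
            "isolated_apical": self.isolated_apical,
            "isolated_septal": self.isolated_septal,
            "combined": self.combined,
        }


def simulate_category_survival(
    table: pd.DataFrame,
    category_column: str,
    effects: CategoryEffects,
    baseline_hazard: float,
    censoring_rate: float = 0.0,
    max_follow_up_years: float = 10.0,
    seed: int = 0,
    outcome: str = "cardiomyopathy",
) -> pd.DataFrame:
    """Survival with hazards driven by hypertrophy category membership."""
    eff = effects.as_dict()
    tmp = table.copy()
    lp_cols = {}
    for name, beta in eff.items():
        col = f"_cat_{name}"
        tmp[col] = (tmp[category_column] == name).astype(float)
        lp_cols[col] = beta
    out = simulate_survival(
        tmp,
        lp_cols,
        baseline_hazard,
        censoring_rate=censoring_rate,
        max_follow_up_years=max_follow_up_years,
        seed=seed,
        outcome=outcome,
    )
    return out.drop(columns=list(lp_cols))
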