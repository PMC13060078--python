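"""Cognitive-resilience scores from a longitudinal mixed model.

The composite cognitive z-score is modeled as

    z_ij = β0 + β1·decade_ij + β2·female_i + β3·(education_i − 12)
           + b0_i + b1_i·decade_ij + ε_ij,

with decade = (age − 70)/10 so β1 is the population decline in SD-units
per decade after age 70, and (b0_i, b1_i) a correlated participant-level
random intercept and slope.  A participant's **resilience score** is
their slope deviation b1_i — the difference between the person-specific
slope (β1 + b1_i) and the overall slope β1 — estimated by its best linear
unbiased prediction (BLUP).  Higher scores mean more stable cognition.

Estimation uses REML via :class:`statsmodels.regression.mixed_linear_model.MixedLM`;
if the full random-effects covariance fails to converge the model is
refit with the intercept–slope correlation fixed at zero and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

__all__ = ["TrajectoryFit", "fit_trajectory", "resilience_scores",
           "per_participant_ols_slopes"]


@dataclass
class TrajectoryFit:
    """Fitted longitudinal model and per-participant slope deviations."""

    intercept: float
    age_slope: float                      # SD-units per decade
    sex_coefficient: float                # female vs male offset
    education_coefficient: float          # per year of education
    random_intercept_sd: float
    random_slope_sd: float                # SD-units per decade
    random_correlation: float
    residual_sd: float
    slope_deviation: pd.Series = field(repr=False)   # index participant_id
    intercept_deviation: pd.Series = field(repr=False)
    converged: bool = True
    correlation_fixed_at_zero: bool = False

    def __post_init__(self) -> None:
        if self.random_intercept_sd < 0 or self.random_slope_sd < 0:
            raise ValueError("random-effect SDs must be non-negative")
        if not abs(self.random_correlation) <= 1 + 1e-9:
            raise ValueError("|random correlation| must be ≤ 1")


def _design(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    req = ["participant_id", "age", "sex", "education", "z"]
    missing = [c for c in req if c not in records.columns]
    if missing:
        raise ValueError(f"cognition records missing columns {missing}")
    dec = (records["age"].to_numpy(float) - 70.0) / 10.0
    female = (records["sex"].astype(str).str.lower()
              .isin(["female", "f", "1", "true"])).to_numpy(float)
    edu = records["education"].to_numpy(float) - 12.0
    X = np.column_stack([np.ones(len(records)), dec, female, edu])
    return X, dec, records["participant_id"]


def fit_trajectory(records: pd.DataFrame, reml: bool = True) -> TrajectoryFit:
    """Fit the mixed model and extract BLUP slope deviations.

    ``records`` is long format with columns participant_id, visit, age,
    sex, education, z.  At least 80% of participants need ≥ 2 visits for
    the slope variance to be identifiable.
    """
    counts = records.groupby("participant_id").size()
    if (counts >= 2).mean() < 0.8:
        raise ValueError("slope unidentifiable: fewer than 80% of participants "
                         "have at least 2 visits")
    X, dec, groups = _design(records)
    y = records["z"].to_numpy(float)

    # degenerate no-noise shortcut: if OLS with common slope fits exactly,
    # there is no heterogeneity to model
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    pids = pd.Index(records["participant_id"].unique(), name="participant_id")
    if float(resid @ resid) / len(y) < 1e-16 * max(1.0, float(y @ y) / len(y)):
        zero = pd.Series(0.0, index=pids)
        return TrajectoryFit(float(beta[0]), float(beta[1]), float(beta[2]),
                             float(beta[3]), 0.0, 0.0, 0.0, 0.0,
                             slope_deviation=zero, intercept_deviation=zero.copy())

    exog_re = np.column_stack([np.ones(len(records)), dec])
    model = MixedLM(y, X, groups=groups.to_numpy(), exog_re=exog_re)
    fixed_corr = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml, method="lbfgs", maxiter=500)
        if not result.converged:
            free = MixedLMParams.from_components(
                fe_params=np.ones(X.shape[1]),
                cov_re=np.eye(2))  # zero off-diagonal => corr fixed at 0
            result = model.fit(reml=reml, free=free, method="lbfgs", maxiter=500)
            fixed_corr = True

    cov_re = np.asarray(result.cov_re)
    sd0 = float(np.sqrt(max(cov_re[0, 0], 0.0)))
    sd1 = float(np.sqrt(max(cov_re[1, 1], 0.0)))
    corr = float(cov_re[0, 1] / (sd0 * sd1)) if sd0 > 0 and sd1 > 0 else 0.0
    corr = float(np.clip(corr, -1.0, 1.0))

    re = result.random_effects
    b0 = pd.Series({k: float(v.iloc[0]) for k, v in re.items()}, name="intercept")
    b1 = pd.Series({k: float(v.iloc[1]) for k, v in re.items()}, name="slope")
    b0 = b0.reindex(pids)
    b1 = b1.reindex(pids)

    fe = np.asarray(result.fe_params, dtype=float)
    return TrajectoryFit(
        intercept=float(fe[0]), age_slope=float(fe[1]),
        sex_coefficient=float(fe[2]), education_coefficient=float(fe[3]),
        random_intercept_sd=sd0, random_slope_sd=sd1, random_correlation=corr,
        residual_sd=float(np.sqrt(result.scale)),
        slope_deviation=b1, intercept_deviation=b0,
        converged=bool(result.converged), correlation_fixed_at_zero=fixed_corr,
    )


def resilience_scores(fit: TrajectoryFit) -> pd.Series:
    """Per-participant resilience: person-specific slope minus overall slope.

    Since the person-specific slope is β1 + b1_i, the score is exactly the
    BLUP slope deviation b1_i (SD-units per decade); the cohort mean is ~0
    under a balanced design.
    """
    s = fit.slope_deviation.copy()
    s.name = "resilience"
    return s


def per_participant_ols_slopes(records: pd.DataFrame) -> pd.Series:
    """Unshrunken per-person OLS slopes (SD-units per decade).

    A sanity oracle for the BLUPs: on low-noise data their ranking agrees.
    Participants with < 2 visits get NaN.
    """
    out = {}
    for pid, grp in records.groupby("participant_id"):
        if len(grp) < 2 or grp["age"].nunique() < 2:
            out[pid] = np.nan
            continue
        dec = (grp["age"].to_numpy(float) - 70.0) / 10.0
        out[pid] = float(np.polyfit(dec, grp["z"].to_numpy(float), 1)[0])
    return pd.Series(out, name="ols_slope")
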