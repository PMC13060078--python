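"""Per-feature inferential stages.

* :func:`lmm_age` — per-feature linear mixed models of log-abundance on
  centered age with participant random intercepts and random age slopes,
  flagging singular fits (random-slope variance on the zero boundary) and
  correcting fixed-slope p-values by Benjamini–Hochberg.
* :func:`hurdle` — the two-step presence/abundance association model:
  step 1 is a logistic regression of detection (area > 0) on the
  resilience score, step 2 an ordinary least-squares regression of
  log-abundance on resilience over the samples where the feature was
  detected.  Each step is BH-corrected within its own family.
* :func:`bh_adjust` — textbook BH step-up with monotonicity enforcement.
* quartile-based resilience grouping, group fold changes with rank-sum
  tests, acylcarnitine chain-length classing, and per-class direction
  summaries of sparse-PLS loading weights.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = ["LmmResult", "HurdleResult", "ChainClass", "lmm_age", "hurdle",
           "bh_adjust", "split_resilience_groups", "fold_change",
           "chain_class", "direction_summary"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j ≥ i} ( m · p_(j) / j ), clipped to 1, order-preserving.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D array")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("bh_adjust: p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Per-feature age mixed models
# ---------------------------------------------------------------------------

@dataclass
class LmmResult:
    feature_id: str
    age_slope: float          # log-abundance per year
    slope_se: float
    p_fixed: float
    q_fixed: float = np.nan
    singular_fit: bool = False
    converged: bool = True


def _fit_one_lmm(y: np.ndarray, age_c: np.ndarray, groups: np.ndarray,
                 het_alpha: float = 0.05) -> tuple[float, float, float, bool, bool]:
    """Random-intercept+slope fit for one feature.

    The 'singular' flag marks absence of detectable slope heterogeneity:
    either the random-slope variance sits on the zero boundary, or the
    REML likelihood-ratio test of that variance (0.5·χ²₀ + 0.5·χ²₁
    boundary mixture) is non-significant at ``het_alpha``.
    """
    X = np.column_stack([np.ones(len(y)), age_c])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = MixedLM(y, X, groups=groups, exog_re=X)
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
            reduced = MixedLM(y, X, groups=groups,
                              exog_re=np.ones((len(y), 1)))
            res0 = reduced.fit(reml=True, method="lbfgs", maxiter=200)
        except (np.linalg.LinAlgError, ValueError):
            ols = sm.OLS(y, X).fit()
            return (float(ols.params[1]), float(ols.bse[1]),
                    float(ols.pvalues[1]), True, False)
    cov_re = np.asarray(res.cov_re)
    total_var = float(np.var(y)) or 1.0
    boundary = cov_re[1, 1] / total_var < 1e-8
    lrt = max(0.0, 2.0 * (res.llf - res0.llf))
    p_het = 0.5 * float(sps.chi2.sf(lrt, df=1)) + (0.5 if lrt <= 0 else 0.0)
    singular = boundary or p_het > het_alpha
    slope = float(res.fe_params[1])
    se = float(res.bse_fe[1])
    p = float(2 * sps.norm.sf(abs(slope / se))) if se > 0 else 1.0
    return slope, se, p, singular, bool(res.converged)


def lmm_age(data: pd.DataFrame, metadata: pd.DataFrame,
            selection_rule: str = "require_singular",
            alpha: float = 0.05, het_alpha: float = 0.05,
            ) -> tuple[pd.DataFrame, dict]:
    """Per-feature mixed model: log-abundance ~ centered age, random
    intercept + random age slope per participant.

    ``data`` is a features × samples log-abundance frame over all visits.
    BH correction runs across features first; ``selection_rule``
    (``require_singular`` / ``require_nonsingular``) then defines the
    reported significant set.  Both counts are returned in the summary so
    either convention is auditable.
    """
    if selection_rule not in ("require_singular", "require_nonsingular"):
        raise ValueError(f"unknown selection_rule '{selection_rule}'")
    meta = metadata.set_index("sample_id").loc[list(data.columns)]
    groups = meta["participant_id"].to_numpy()
    if pd.Series(groups).value_counts().max() < 2:
        raise ValueError("lmm_age: no participant has ≥ 2 visits")
    age = meta["age"].to_numpy(float)
    age_c = age - age.mean()

    rows = []
    for fid in data.index:
        y = data.loc[fid].to_numpy(float)
        ok = ~np.isnan(y)
        slope, se, p, singular, conv = _fit_one_lmm(
            y[ok], age_c[ok], groups[ok], het_alpha)
        rows.append(LmmResult(fid, slope, se, p, singular_fit=singular,
                              converged=conv))
    df = pd.DataFrame([vars(r) for r in rows]).set_index("feature_id")
    df["q_fixed"] = bh_adjust(df["p_fixed"].to_numpy())
    sig = df["q_fixed"] < alpha
    n_sig_singular = int((sig & df["singular_fit"]).sum())
    n_sig_nonsingular = int((sig & ~df["singular_fit"]).sum())
    if selection_rule == "require_singular":
        df["selected"] = sig & df["singular_fit"]
    else:
        df["selected"] = sig & ~df["singular_fit"]
    summary = {"n_features": len(df), "alpha": alpha,
               "selection_rule": selection_rule,
               "n_significant": int(sig.sum()),
               "n_significant_singular": n_sig_singular,
               "n_significant_nonsingular": n_sig_nonsingular,
               "n_selected": int(df["selected"].sum())}
    return df, summary


# ---------------------------------------------------------------------------
# Hurdle model
# ---------------------------------------------------------------------------

@dataclass
class HurdleResult:
    feature_id: str
    step1_coef: float = np.nan      # presence log-odds per resilience unit
    p1: float = np.nan
    q1: float = np.nan
    step2_coef: float = np.nan      # log-abundance slope per resilience unit
    p2: float = np.nan
    q2: float = np.nan
    n_present: int = 0
    n_absent: int = 0
    step1_estimable: bool = False
    step2_estimable: bool = False


def _logistic_lrt(present: np.ndarray, x: np.ndarray,
                  max_abs_coef: float = 50.0) -> tuple[float, float, bool]:
    """Logistic regression of presence on x with a likelihood-ratio p.

    Returns (coefficient, p, ok); ok is False under (quasi-)separation,
    detected by divergent coefficients or non-convergence.
    """
    X = np.column_stack([np.ones(len(x)), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = sm.Logit(present, X).fit(disp=0, maxiter=100)
        except Exception:
            return np.nan, np.nan, False
    if not full.mle_retvals.get("converged", False):
        return np.nan, np.nan, False
    coef = float(full.params[1])
    if abs(coef) > max_abs_coef:
        return coef, np.nan, False
    pbar = present.mean()
    ll_null = len(present) * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
    lr = 2 * (full.llf - ll_null)
    p = float(sps.chi2.sf(max(lr, 0.0), df=1))
    return coef, p, True


def hurdle(table, resilience: pd.Series, min_group: int = 5,
           alpha: float = 0.05) -> pd.DataFrame:
    """Two-step hurdle association of each feature with resilience.

    ``table`` is a :class:`~resilmet.io.FeatureTable` (or an areas frame)
    restricted to the selected visit, columns aligned with the sample
    index of ``resilience``.  Step 1 regresses detection (area > 0) on
    resilience by logistic regression, skipped when either presence group
    has fewer than ``min_group`` samples or separation is detected.  Step
    2 regresses ln(area) on resilience over the detected samples.  BH runs
    within each step over estimable features.
    """
    areas = table.areas if hasattr(table, "areas") else table
    samples = [s for s in areas.columns if s in resilience.index]
    if len(samples) < areas.shape[1]:
        areas = areas[samples]
    r = resilience.loc[areas.columns].to_numpy(float)
    if np.ptp(r) == 0:
        raise ValueError("hurdle: resilience score is constant")

    rows = []
    for fid in areas.index:
        a = areas.loc[fid].to_numpy(float)
        present = a > 0
        res = HurdleResult(fid, n_present=int(present.sum()),
                           n_absent=int((~present).sum()))
        if min(res.n_present, res.n_absent) >= min_group:
            coef, p, ok = _logistic_lrt(present.astype(float), r)
            if ok:
                res.step1_coef, res.p1, res.step1_estimable = coef, p, True
            else:
                res.step1_coef = coef
        if res.n_present >= 3 and np.ptp(r[present]) > 0:
            slope, _, _, p2, _ = sps.linregress(r[present], np.log(a[present]))
            res.step2_coef, res.p2, res.step2_estimable = float(slope), float(p2), True
        rows.append(res)

    df = pd.DataFrame([vars(x) for x in rows]).set_index("feature_id")
    for step, (pcol, qcol, flag) in enumerate(
            [("p1", "q1", "step1_estimable"), ("p2", "q2", "step2_estimable")]):
        mask = df[flag].to_numpy(bool)
        if mask.any():
            df.loc[mask, qcol] = bh_adjust(df.loc[mask, pcol].to_numpy())
    assert ((df["n_present"] + df["n_absent"]) == len(areas.columns)).all()
    return df


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def split_resilience_groups(resilience: pd.Series) -> pd.Series:
    """Median split: lower two quartiles → 'low', upper two → 'high'.

    Samples tied at the median go to the low group; with distinct scores
    the group sizes differ by at most one.
    """
    if len(resilience) < 4:
        raise ValueError("split_resilience_groups: need at least 4 samples")
    med = float(resilience.median())
    labels = pd.Series(np.where(resilience.to_numpy(float) <= med, "low", "high"),
                       index=resilience.index, name="resilience_group")
    return labels


def fold_change(table, groups: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature log2 fold change (high vs low) with rank-sum tests.

    Means are computed on raw areas over detected (non-zero) samples; the
    two-sided Wilcoxon rank-sum test runs on log areas.  A feature absent
    in one whole group gets an infinite-coded FC and no test.
    """
    areas = table.areas if hasattr(table, "areas") else table
    groups = groups.loc[[c for c in areas.columns if c in groups.index]]
    lo = [s for s in groups.index if groups[s] == "low"]
    hi = [s for s in groups.index if groups[s] == "high"]
    if not lo or not hi:
        raise ValueError("fold_change: both groups must be non-empty")
    rows = []
    for fid in areas.index:
        a_lo = areas.loc[fid, lo].to_numpy(float)
        a_hi = areas.loc[fid, hi].to_numpy(float)
        nz_lo, nz_hi = a_lo[a_lo > 0], a_hi[a_hi > 0]
        if nz_lo.size == 0 and nz_hi.size == 0:
            fc, p, tested = np.nan, np.nan, False
        elif nz_lo.size == 0:
            fc, p, tested = np.inf, np.nan, False
        elif nz_hi.size == 0:
            fc, p, tested = -np.inf, np.nan, False
        else:
            fc = float(np.log2(nz_hi.mean() / nz_lo.mean()))
            p = float(sps.ranksums(np.log(nz_hi), np.log(nz_lo)).pvalue)
            tested = True
        rows.append({"feature_id": fid, "log2_fc": fc, "p": p, "tested": tested,
                     "n_low_detected": int(nz_lo.size),
                     "n_high_detected": int(nz_hi.size)})
    df = pd.DataFrame(rows).set_index("feature_id")
    mask = df["tested"].to_numpy(bool)
    df["q"] = np.nan
    if mask.any():
        df.loc[mask, "q"] = bh_adjust(df.loc[mask, "p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Acylcarnitine chain classes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainClass:
    carbon_count: int | None
    unsaturation: int | None
    chain_class: str      # short | medium | long | very_long | unknown


_CHAIN_TOKEN = re.compile(r"\bC(\d+)(?::(\d+))?\b")


def chain_class(annotation: str) -> ChainClass:
    """Parse a carbon-chain token like ``"C12:1"`` and class its length.

    Classes: short C2–C5, medium C6–C12, long C13–C21, very long ≥ C22.
    Unparseable annotations map to ``unknown``.
    """
    m = _CHAIN_TOKEN.search(annotation or "")
    if not m:
        return ChainClass(None, None, "unknown")
    carbons = int(m.group(1))
    unsat = int(m.group(2)) if m.group(2) is not None else 0
    if 2 <= carbons <= 5:
        cls = "short"
    elif 6 <= carbons <= 12:
        cls = "medium"
    elif 13 <= carbons <= 21:
        cls = "long"
    elif carbons >= 22:
        cls = "very_long"
    else:
        cls = "unknown"
    return ChainClass(carbons, unsat, cls)


def direction_summary(weights: pd.Series, class_labels: pd.Series) -> pd.Series:
    """Per-class fraction of features with negative loading weight."""
    common = weights.index.intersection(class_labels.index)
    if common.empty:
        raise ValueError("direction_summary: no overlapping features")
    out = {}
    for cls, members in class_labels.loc[common].groupby(class_labels.loc[common]):
        w = weights.loc[members.index]
        if len(w) == 0:
            raise ValueError(f"direction_summary: empty class '{cls}'")
        out[cls] = float((w < 0).mean())
    return pd.Series(out, name="fraction_negative")
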