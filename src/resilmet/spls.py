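"""One-component sparse partial least squares regression (sPLS-1).

For a single response and one latent component, the sparse PLS loading
weight is the soft-thresholded cross-covariance X'y keeping the ``keep``
largest-magnitude entries, renormalized to unit length; the latent score
is t = Xw and the response is regressed on t.  Selection is therefore
exactly "top-|covariance|" — which doubles as an independent brute-force
oracle in the tests.

Also here: keep-tuning by a unit-invariant knee on the ranked
|covariance| curve refined by cross-validated RMSE (one-standard-error
rule), k-fold cross-validation with per-fold selection stability,
permutation testing of R², and external validation (Jaccard overlap and
loading-weight correlation between independently refit models).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["SplsFit", "CvResult", "TuneResult", "PermutationResult",
           "ExternalValidation", "prepare_matrix", "fit_spls1",
           "cross_validate", "tune_keep", "permutation_test",
           "external_validate", "jaccard"]


@dataclass
class SplsFit:
    """A fitted one-component sparse PLS model."""

    weights: pd.Series = field(repr=False)       # per-feature loading weight, 0 if unselected
    scores: np.ndarray = field(repr=False)       # latent score t = Xc @ w
    y_coefficient: float = 0.0                   # slope of y on t
    y_intercept: float = 0.0
    r2: float = 0.0                              # in-sample variance explained
    rmse: float = 0.0
    p_value: float = 1.0                         # F-test of y ~ t
    keep: int = 0
    scaled: bool = True
    column_means: pd.Series = field(default=None, repr=False)
    column_scales: pd.Series = field(default=None, repr=False)
    n_components: int = 1

    @property
    def selected_set(self) -> set[str]:
        return set(self.weights.index[self.weights.to_numpy() != 0.0])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xc = (X[self.weights.index] - self.column_means) / self.column_scales
        t = Xc.to_numpy(float) @ self.weights.to_numpy(float)
        return self.y_intercept + self.y_coefficient * t


def prepare_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Features × samples frame (NaN = missing) → samples × features matrix
    with missing entries mean-filled per feature."""
    X = data.T.copy()
    means = X.mean(axis=0, skipna=True)
    return X.fillna(means)


def _center_scale(X: np.ndarray, scale: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    Xc = X - mu
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
    else:
        sd = np.ones(X.shape[1])
    return Xc / sd, mu, sd


def fit_spls1(X: pd.DataFrame, y: np.ndarray | pd.Series, keep: int,
              scale: bool = True) -> SplsFit:
    """Fit the one-component sparse PLS of y on X (samples × features).

    ``keep`` is the number of features retained in the loading-weight
    vector.  Columns are centered (and unit-variance scaled by default);
    missing values must already be filled (see :func:`prepare_matrix`).
    """
    Xv = X.to_numpy(float)
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if np.isnan(Xv).any():
        raise ValueError("fit_spls1: X contains missing values; use prepare_matrix")
    if not 1 <= keep <= p:
        raise ValueError(f"fit_spls1: keep must lie in [1, {p}]")
    if np.std(yv) == 0:
        raise ValueError("fit_spls1: response has zero variance")

    Xs, mu, sd = _center_scale(Xv, scale)
    yc = yv - yv.mean()
    c = Xs.T @ yc / (n - 1)                       # cross-covariance
    order = np.argsort(-np.abs(c), kind="stable")
    w = np.zeros(p)
    sel = order[:keep]
    w[sel] = c[sel]
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("fit_spls1: all selected covariances are zero")
    w /= nrm

    t = Xs @ w
    slope, intercept, r, p_r, _ = sps.linregress(t, yv)
    yhat = intercept + slope * t
    resid = yv - yhat
    return SplsFit(
        weights=pd.Series(w, index=X.columns, name="weight"),
        scores=t, y_coefficient=float(slope), y_intercept=float(intercept),
        r2=float(r ** 2), rmse=float(np.sqrt(np.mean(resid ** 2))),
        p_value=float(p_r), keep=keep, scaled=scale,
        column_means=pd.Series(mu, index=X.columns),
        column_scales=pd.Series(sd, index=X.columns),
    )


@dataclass
class CvResult:
    """Out-of-fold performance and per-feature selection stability."""

    observed_r: float
    cv_r2: float
    rmse: float
    stability: pd.Series = field(repr=False)     # fraction of folds selected
    fold_selected: list[set[str]] = field(default_factory=list, repr=False)
    n_folds: int = 10


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def cross_validate(X: pd.DataFrame, y: np.ndarray | pd.Series, keep: int,
                   k: int = 10, seed: int = 0, scale: bool = True) -> CvResult:
    """k-fold CV: assemble out-of-fold predictions and per-fold selections."""
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if n < 2 * k:
        raise ValueError(f"cross_validate: need n ≥ 2k (n={n}, k={k})")
    rng = np.random.default_rng(seed)
    folds = _fold_indices(n, k, rng)
    yhat = np.full(n, np.nan)
    counts = pd.Series(0.0, index=X.columns)
    fold_sets: list[set[str]] = []
    used_folds = 0
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if np.std(yv[train_idx]) == 0:
            continue
        fit = fit_spls1(X.iloc[train_idx], yv[train_idx], keep, scale=scale)
        yhat[test_idx] = fit.predict(X.iloc[test_idx])
        sel = fit.selected_set
        counts[list(sel)] += 1
        fold_sets.append(sel)
        used_folds += 1
    ok = ~np.isnan(yhat)
    r = float(np.corrcoef(yv[ok], yhat[ok])[0, 1]) if ok.sum() > 2 else np.nan
    rmse = float(np.sqrt(np.mean((yv[ok] - yhat[ok]) ** 2)))
    return CvResult(observed_r=r, cv_r2=float(r ** 2), rmse=rmse,
                    stability=counts / max(used_folds, 1),
                    fold_selected=fold_sets, n_folds=used_folds)


@dataclass
class TuneResult:
    keep: int
    knee: int | None
    grid: list[int]
    cv_rmse: dict[int, float]
    cv_rmse_se: dict[int, float]
    fallback_cv_only: bool = False


def _knee_index(curve: np.ndarray) -> int | None:
    """Unit-invariant knee of a decreasing curve: the point farthest below
    the chord joining its endpoints after normalizing both axes to [0,1]."""
    m = len(curve)
    if m < 3 or curve[0] == curve[-1]:
        return None
    x = np.linspace(0.0, 1.0, m)
    ynorm = (curve - curve[-1]) / (curve[0] - curve[-1])
    chord = 1.0 - x
    gap = chord - ynorm
    return int(np.argmax(gap))


def tune_keep(X: pd.DataFrame, y: np.ndarray | pd.Series,
              grid: list[int] | None = None, folds: int = 10,
              seed: int = 0, scale: bool = True) -> TuneResult:
    """Choose the sparsity level ``keep``.

    Features are ranked by |cov(x_j, y)|; the knee of the ranked-magnitude
    curve seeds a candidate grid, which is scored by cross-validated RMSE;
    the smallest keep within one standard error of the minimum wins.
    """
    yv = np.asarray(y, dtype=float)
    Xs, _, _ = _center_scale(X.to_numpy(float), scale)
    c = np.abs(Xs.T @ (yv - yv.mean()) / (len(yv) - 1))
    ranked = np.sort(c)[::-1]
    p = len(ranked)

    fallback = False
    if grid is None:
        knee = _knee_index(ranked)
        if knee is None:
            fallback = True
            grid = sorted({max(1, int(round(p * f))) for f in
                           (0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0)})
        else:
            k0 = max(1, knee + 1)
            grid = sorted({max(1, min(p, int(round(k0 * f))))
                           for f in (0.25, 0.5, 1.0, 2.0, 4.0)})
    else:
        knee = _knee_index(ranked)
        grid = sorted(set(int(k) for k in grid))
        if not grid:
            raise ValueError("tune_keep: empty grid")
    if len(grid) == 1:
        return TuneResult(grid[0], knee, grid, {}, {}, fallback)

    rmse: dict[int, float] = {}
    se: dict[int, float] = {}
    for k in grid:
        cv = cross_validate(X, yv, k, k=folds, seed=seed, scale=scale)
        per_fold = []
        rng = np.random.default_rng(seed)
        folds_idx = _fold_indices(len(yv), folds, rng)
        # per-fold RMSEs for the one-SE rule
        for test_idx in folds_idx:
            train_idx = np.setdiff1d(np.arange(len(yv)), test_idx)
            fit = fit_spls1(X.iloc[train_idx], yv[train_idx], k, scale=scale)
            pred = fit.predict(X.iloc[test_idx])
            per_fold.append(float(np.sqrt(np.mean((yv[test_idx] - pred) ** 2))))
        rmse[k] = cv.rmse
        se[k] = float(np.std(per_fold, ddof=1) / np.sqrt(len(per_fold)))
    best = min(rmse, key=rmse.get)
    threshold = rmse[best] + se[best]
    chosen = min(k for k in grid if rmse[k] <= threshold)
    return TuneResult(chosen, knee, grid, rmse, se, fallback)


@dataclass
class PermutationResult:
    p_value: float
    r2_observed: float
    r2_permuted: np.ndarray = field(repr=False)
    n_permutations: int = 100


def permutation_test(X: pd.DataFrame, y: np.ndarray | pd.Series, keep: int,
                     n_perm: int = 100, seed: int = 0,
                     scale: bool = True) -> PermutationResult:
    """Permutation null for the model R²: p = (1 + #{R²_perm ≥ R²_obs}) / (n_perm + 1)."""
    if n_perm < 1:
        raise ValueError("permutation_test: n_perm must be ≥ 1")
    yv = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    r2_obs = fit_spls1(X, yv, keep, scale=scale).r2
    r2_perm = np.empty(n_perm)
    for b in range(n_perm):
        r2_perm[b] = fit_spls1(X, rng.permutation(yv), keep, scale=scale).r2
    p = (1 + int((r2_perm >= r2_obs).sum())) / (n_perm + 1)
    return PermutationResult(float(p), float(r2_obs), r2_perm, n_perm)


def jaccard(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|; undefined (error) when both sets are empty."""
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


@dataclass
class ExternalValidation:
    """Agreement between the original fit and an external-visit refit."""

    r2_ext: float
    p_ext: float
    cv_r_ext: float
    jaccard: float
    loading_correlation: float
    top_weight_reselection: float        # fraction of top-5% |w| reselected
    overall_reselection: float           # fraction of all selected reselected


def external_validate(fit: SplsFit, X_ext: pd.DataFrame,
                      y_ext: np.ndarray | pd.Series, folds: int = 10,
                      seed: int = 0) -> ExternalValidation:
    """Validate a fitted model on an external sample selection.

    (a) project the external data on the original weights → R² and its
    regression p; (b) k-fold CV observed r on the external data; (c) refit
    with identical parameters → Jaccard of selected sets and Pearson
    correlation of loading weights over the union of both selected sets
    (unselected entries = 0); (d) reselection fraction among the top 5% of
    original |weights|.
    """
    missing = set(fit.weights.index) - set(X_ext.columns)
    if missing:
        raise ValueError(f"external data lacks features: {sorted(missing)[:5]}")
    X_ext = X_ext[fit.weights.index]
    yv = np.asarray(y_ext, dtype=float)

    pred = fit.predict(X_ext)
    _, _, r, p_r, _ = sps.linregress(pred, yv)
    cv = cross_validate(X_ext, yv, fit.keep, k=folds, seed=seed, scale=fit.scaled)
    refit = fit_spls1(X_ext, yv, fit.keep, scale=fit.scaled)

    sel_a, sel_b = fit.selected_set, refit.selected_set
    union = sorted(sel_a | sel_b)
    wa = fit.weights[union].to_numpy(float)
    wb = refit.weights[union].to_numpy(float)
    load_corr = float(np.corrcoef(wa, wb)[0, 1]) if len(union) > 1 else np.nan

    w_abs = fit.weights.abs()
    n_top = max(1, int(round(0.05 * fit.keep)))
    top = set(w_abs[w_abs > 0].sort_values(ascending=False).index[:n_top])
    top_frac = len(top & sel_b) / len(top)
    overall = len(sel_a & sel_b) / len(sel_a)
    return ExternalValidation(
        r2_ext=float(r ** 2), p_ext=float(p_r), cv_r_ext=float(cv.observed_r),
        jaccard=jaccard(sel_a, sel_b), loading_correlation=load_corr,
        top_weight_reselection=float(top_frac), overall_reselection=float(overall),
    )
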