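"""Feature-table conditioning for the two analysis branches.

The sparse-PLS (resilience) branch runs: dead-volume filter → blank
filter → single-visit selection (minimizing the age SD across
participants) → robust centered log-ratio (RCLR) → age residualization →
near-zero-variance removal.  The mixed-model (aging) branch runs:
dead-volume filter → blank filter → sparsity filter → per-feature
pseudocount (half the minimum non-zero area) → natural log.

Filters operate on :class:`~resilmet.io.FeatureTable` and return new
tables; transforms return a features × samples ``DataFrame`` in which
NaN marks a value that was not detected (RCLR treats zeros as missing).
A :class:`PreprocessReport` records each step's survivor counts and
parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureTable

__all__ = [
    "PreprocessReport", "dead_volume_filter", "blank_filter",
    "sparsity_filter", "pseudocount_log", "rclr", "residualize_covariate",
    "nzv_filter", "select_visit_min_age_sd", "select_external_visit",
    "spls_branch", "lmm_branch",
]


@dataclass
class PreprocessReport:
    """Step-by-step record of a preprocessing run."""

    steps: list[dict] = field(default_factory=list)
    selected_visits: dict[str, object] = field(default_factory=dict)
    external_visits: dict[str, object] = field(default_factory=dict)
    achieved_age_sd: float | None = None
    dropped_participants: list[str] = field(default_factory=list)

    def record(self, step: str, n_in: int, n_out: int, **params) -> None:
        if self.steps and n_out > n_in:
            raise ValueError(f"step '{step}' increased the feature count")
        self.steps.append({"step": step, "n_in": n_in, "n_out": n_out,
                           "params": params})


def dead_volume_filter(table: FeatureTable, rt_min: float = 0.7,
                       report: PreprocessReport | None = None) -> FeatureTable:
    """Drop features eluting before ``rt_min`` minutes (dead volume)."""
    keep = table.feature_ids[table.rt.to_numpy(float) >= rt_min]
    out = table.subset_features(keep)
    if report is not None:
        report.record("dead_volume", len(table.feature_ids), len(keep), rt_min=rt_min)
    return out


def _nonzero_agg(values: np.ndarray, how: str) -> float:
    nz = values[values > 0]
    if nz.size == 0:
        return 0.0
    return float(nz.mean() if how == "mean" else nz.max())


def blank_filter(table: FeatureTable, metadata: pd.DataFrame,
                 factor: float = 5.0, aggregate: str = "mean",
                 report: PreprocessReport | None = None) -> FeatureTable:
    """Drop features without ``factor``-fold the blank-channel signal.

    A feature is kept iff aggregate(non-zero sample areas) ≥
    factor × aggregate(non-zero blank areas); ``aggregate`` is mean or
    max.  A feature never seen in blanks (blank aggregate 0) is kept.
    """
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be 'mean' or 'max'")
    meta = metadata.set_index("sample_id")
    is_blank = meta.loc[table.sample_ids, "is_blank"].astype(bool).to_numpy()
    if not is_blank.any():
        raise ValueError(
            "blank_filter: no blank samples flagged; skip this step explicitly "
            "if the experiment has no blank channels")
    areas = table.areas.to_numpy(float)
    keep_mask = np.empty(areas.shape[0], dtype=bool)
    for i in range(areas.shape[0]):
        blank = _nonzero_agg(areas[i, is_blank], aggregate)
        samp = _nonzero_agg(areas[i, ~is_blank], aggregate)
        keep_mask[i] = blank == 0.0 or samp >= factor * blank
    out = table.subset_features(table.feature_ids[keep_mask])
    if report is not None:
        report.record("blank_filter", len(table.feature_ids), int(keep_mask.sum()),
                      factor=factor, aggregate=aggregate)
    return out


def sparsity_filter(table: FeatureTable, min_presence_frac: float,
                    metadata: pd.DataFrame | None = None,
                    report: PreprocessReport | None = None) -> FeatureTable:
    """Keep features present (area > 0) in at least the given fraction of
    non-blank samples."""
    if not 0 < min_presence_frac <= 1:
        raise ValueError("min_presence_frac must lie in (0, 1]")
    areas = table.areas
    if metadata is not None:
        meta = metadata.set_index("sample_id")
        nb = [s for s in table.sample_ids if not bool(meta.loc[s, "is_blank"])]
        areas = areas[nb]
    frac = (areas.to_numpy(float) > 0).mean(axis=1)
    keep = table.feature_ids[frac >= min_presence_frac]
    out = table.subset_features(keep)
    if report is not None:
        report.record("sparsity", len(table.feature_ids), len(keep),
                      min_presence_frac=min_presence_frac)
    return out


def pseudocount_log(table: FeatureTable) -> pd.DataFrame:
    """Replace zeros by half the per-feature minimum non-zero area, then ln."""
    areas = table.areas.to_numpy(float).copy()
    for i in range(areas.shape[0]):
        nz = areas[i][areas[i] > 0]
        if nz.size == 0:
            raise ValueError(
                f"pseudocount_log: feature '{table.feature_ids[i]}' is all-zero; "
                "apply a sparsity filter first")
        areas[i][areas[i] == 0] = nz.min() / 2.0
    return pd.DataFrame(np.log(areas), index=table.feature_ids,
                        columns=table.sample_ids)


def rclr(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    """Robust centered log-ratio transform, per sample over observed entries.

    For each sample (column), observed entries become
    ln(area) − mean(ln(area) over that sample's non-zero entries); zeros
    become NaN (missing) and are excluded from the mean.  This is the
    standard compositional transform for zero-inflated LC-MS tables.
    """
    areas = table.areas if isinstance(table, FeatureTable) else table
    vals = areas.to_numpy(float)
    if (vals < 0).any():
        raise ValueError("rclr: negative areas")
    obs = vals > 0
    if (obs.sum(axis=0) < 2).any():
        j = int(np.argmax(obs.sum(axis=0) < 2))
        raise ValueError(f"rclr: sample '{areas.columns[j]}' has fewer than 2 "
                         "observed features")
    with np.errstate(divide="ignore"):
        logv = np.where(obs, np.log(np.where(obs, vals, 1.0)), np.nan)
    centered = logv - np.nanmean(logv, axis=0, keepdims=True)
    return pd.DataFrame(centered, index=areas.index, columns=areas.columns)


def residualize_covariate(data: pd.DataFrame, metadata: pd.DataFrame,
                          covariate: str = "age") -> pd.DataFrame:
    """Replace each feature by residuals of its regression on a covariate.

    The simple per-feature linear regression is fit over observed
    (non-NaN) entries only; NaNs stay NaN.  A constant covariate returns
    the input unchanged with a warning.
    """
    meta = metadata.set_index("sample_id")
    cov = meta.loc[data.columns, covariate].to_numpy(float)
    if np.isnan(cov).any():
        bad = data.columns[int(np.argmax(np.isnan(cov)))]
        raise ValueError(f"residualize_covariate: sample '{bad}' lacks '{covariate}'")
    if np.ptp(cov) == 0:
        warnings.warn(f"covariate '{covariate}' is constant; returning data unchanged")
        return data.copy()
    vals = data.to_numpy(float).copy()
    for i in range(vals.shape[0]):
        row = vals[i]
        m = ~np.isnan(row)
        if m.sum() < 2 or np.ptp(cov[m]) == 0:
            continue
        slope, intercept = np.polyfit(cov[m], row[m], 1)
        vals[i, m] = row[m] - (intercept + slope * cov[m])
    return pd.DataFrame(vals, index=data.index, columns=data.columns)


def nzv_filter(data: pd.DataFrame, var_eps: float = 1e-8,
               dominance: float = 0.95,
               report: PreprocessReport | None = None) -> pd.DataFrame:
    """Drop near-zero-variance features.

    A feature is removed if its variance over observed entries is below
    ``var_eps`` or its most frequent observed value occupies more than
    ``dominance`` of the samples.
    """
    vals = data.to_numpy(float)
    keep = np.ones(vals.shape[0], dtype=bool)
    for i in range(vals.shape[0]):
        row = vals[i][~np.isnan(vals[i])]
        if row.size < 2 or np.var(row) < var_eps:
            keep[i] = False
            continue
        _, counts = np.unique(row, return_counts=True)
        if counts.max() / vals.shape[1] > dominance:
            keep[i] = False
    out = data.loc[keep]
    if report is not None:
        report.record("nzv", vals.shape[0], int(keep.sum()),
                      var_eps=var_eps, dominance=dominance)
    return out


# ---------------------------------------------------------------------------
# Visit selection
# ---------------------------------------------------------------------------

def _cohort_sd(ages: np.ndarray) -> float:
    return float(np.std(ages))


def select_visit_min_age_sd(metadata: pd.DataFrame,
                            max_sweeps: int = 100,
                            ) -> tuple[dict[str, object], float]:
    """Pick one visit per participant minimizing the cohort SD of age.

    Coordinate descent: starting from each uniform visit index (best kept),
    repeatedly re-choose each participant's visit to minimize the cohort
    age SD until a fixed point; ties break toward the earlier visit.  The
    achieved SD is never worse than the best uniform-visit SD.
    Deterministic given input order.
    """
    nb = metadata.loc[~metadata["is_blank"].astype(bool)]
    pids = list(dict.fromkeys(nb["participant_id"]))
    visits = {p: sorted(zip(g["visit"], g["age"].astype(float)))
              for p, g in nb.groupby("participant_id", sort=False)}
    max_nv = max(len(v) for v in visits.values())
    n = len(pids)

    def descend(choice: dict) -> tuple[dict, float]:
        choice = dict(choice)
        ages = {p: visits[p][choice[p]][1] for p in pids}
        s1 = sum(ages.values())
        s2 = sum(a * a for a in ages.values())
        for _ in range(max_sweeps):
            changed = False
            for p in pids:
                cur = ages[p]
                base1, base2 = s1 - cur, s2 - cur * cur
                best_j, best_var = choice[p], None
                for j, (_, a) in enumerate(visits[p]):
                    t1, t2 = base1 + a, base2 + a * a
                    var = t2 / n - (t1 / n) ** 2
                    if best_var is None or var < best_var - 1e-15:
                        best_var, best_j = var, j
                if best_j != choice[p]:
                    choice[p] = best_j
                    a = visits[p][best_j][1]
                    s1, s2 = base1 + a, base2 + a * a
                    ages[p] = a
                    changed = True
            if not changed:
                break
        final = np.array([ages[p] for p in pids])
        return choice, _cohort_sd(final)

    # initializations: every uniform visit index, plus the closest-to-target
    # assignment for every target age at which that assignment changes (the
    # midpoints between a participant's consecutive ages).  Any coordinate-
    # descent fixed point assigns each participant the age closest to the
    # mean of the others, so these starts cover the basin of the optimum.
    starts: list[dict] = [
        {p: min(i, len(visits[p]) - 1) for p in pids} for i in range(max_nv)
    ]
    targets: set[float] = set()
    for p in pids:
        ages_p = [a for _, a in visits[p]]
        targets.update(ages_p)
        targets.update((a + b) / 2 for a, b in zip(ages_p, ages_p[1:]))
    for t in sorted(targets):
        starts.append({
            p: min(range(len(visits[p])),
                   key=lambda j: (abs(visits[p][j][1] - t), j))
            for p in pids
        })

    best_choice, best_sd = None, np.inf
    for init in starts:
        choice, sd = descend(init)
        if sd < best_sd - 1e-12:
            best_choice, best_sd = choice, sd
    sel = {p: visits[p][best_choice[p]][0] for p in pids}
    return sel, best_sd


def select_external_visit(metadata: pd.DataFrame,
                          selected: dict[str, object],
                          report: PreprocessReport | None = None,
                          ) -> dict[str, object]:
    """Per participant, the unselected visit closest in age to the selected one.

    Ties break toward the earlier visit.  Single-visit participants are
    dropped with a warning (listed in the report).
    """
    nb = metadata.loc[~metadata["is_blank"].astype(bool)]
    out: dict[str, object] = {}
    dropped: list[str] = []
    for p, g in nb.groupby("participant_id", sort=False):
        vs = sorted(zip(g["visit"], g["age"].astype(float)))
        if p not in selected:
            continue
        if len(vs) < 2:
            dropped.append(str(p))
            continue
        sel_age = dict(vs)[selected[p]]
        cands = [(abs(a - sel_age), v, a) for v, a in vs if v != selected[p]]
        cands.sort(key=lambda t: (t[0], t[1]))
        out[p] = cands[0][1]
    if dropped:
        warnings.warn(f"{len(dropped)} single-visit participants dropped from "
                      "external validation")
    if report is not None:
        report.external_visits = dict(out)
        report.dropped_participants.extend(dropped)
    return out


# ---------------------------------------------------------------------------
# Branch drivers
# ---------------------------------------------------------------------------

def spls_branch(table: FeatureTable, metadata: pd.DataFrame,
                rt_min: float = 0.7, blank_factor: float = 5.0,
                blank_aggregate: str = "mean", min_presence: float = 0.4,
                nzv_var_eps: float = 1e-8, nzv_dominance: float = 0.95,
                visit_map: dict | None = None,
                ) -> tuple[pd.DataFrame, pd.DataFrame, PreprocessReport]:
    """Full resilience-branch conditioning.

    Returns (processed features × selected-samples frame with NaN for
    missing, the metadata subset for the selected samples, report).
    """
    report = PreprocessReport()
    t = dead_volume_filter(table, rt_min, report)
    t = blank_filter(t, metadata, blank_factor, blank_aggregate, report)

    if visit_map is None:
        visit_map, sd = select_visit_min_age_sd(metadata)
        report.achieved_age_sd = sd
    report.selected_visits = dict(visit_map)
    nb = metadata.loc[~metadata["is_blank"].astype(bool)]
    sel_samples = [row["sample_id"] for _, row in nb.iterrows()
                   if visit_map.get(row["participant_id"]) == row["visit"]]
    t = t.subset_samples(sel_samples)
    t = sparsity_filter(t, min_presence, report=report)

    x = rclr(t)
    x = residualize_covariate(x, metadata, "age")
    x = nzv_filter(x, nzv_var_eps, nzv_dominance, report)
    meta_sel = nb.set_index("sample_id").loc[sel_samples].reset_index()
    return x, meta_sel, report


def lmm_branch(table: FeatureTable, metadata: pd.DataFrame,
               rt_min: float = 0.7, blank_factor: float = 5.0,
               blank_aggregate: str = "mean", min_presence: float = 0.3,
               ) -> tuple[pd.DataFrame, pd.DataFrame, PreprocessReport]:
    """Aging-branch conditioning over all visits: filters → pseudocount/log."""
    report = PreprocessReport()
    t = dead_volume_filter(table, rt_min, report)
    t = blank_filter(t, metadata, blank_factor, blank_aggregate, report)
    nb_samples = metadata.loc[~metadata["is_blank"].astype(bool), "sample_id"]
    t = t.subset_samples(list(nb_samples))
    t = sparsity_filter(t, min_presence, report=report)
    x = pseudocount_log(t)
    meta_nb = metadata.loc[~metadata["is_blank"].astype(bool)].reset_index(drop=True)
    return x, meta_nb, report
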