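"""Synthetic cohort generator: cognition records, LC-MS feature table, MS/MS spectra.

The generator emulates the data structures of a longitudinal aging cohort
with serum metabolomics:

* **Cognition** — composite z-scores per participant-visit from a linear
  mixed model with fixed age / sex / education effects and correlated
  random intercepts and slopes.  The population decline is −0.7 SD per
  decade after age 70; each participant's *true* random-slope deviation is
  recorded so downstream estimation can be scored against truth.
* **Feature table** — log-normal peak areas with a hard detection limit
  (areas below it become 0, yielding informative presence/absence);
  planted subsets of features carry linear terms in the participant's true
  slope deviation ("resilience features") or in age ("age features");
  blank channels carry a few contaminant features at high level.
* **Spectra** — MS/MS records with planted glucuronide neutral losses
  (176.0321 / 194.0425 Da), two β-blocker-like parent drugs carrying the
  shared aryloxypropanolamine backbone fragments (m/z 72.0806, 98.0964,
  116.1070, 133.0643), their metabolites (delta-mass-shifted precursors,
  earlier retention time, occurrence nested in the parent's samples), and
  distractors each violating exactly one of those properties.

Everything is deterministic under ``config.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .io import FeatureTable, SpectrumRecord
from .spectra import BACKBONE_FRAGMENTS, GLUCURONIDE_LOSS, WATER_GLUCURONIDE_LOSS, \
    default_modification_table

__all__ = ["GroundTruth", "generate_cohort", "generate_feature_table",
           "generate_spectra", "generate_all"]

#: the two synthetic β-blocker parents: (id, precursor m/z, rt minutes)
PARENT_DRUGS = [("parent_metoprolol", 268.1907, 6.0),
                ("parent_atenolol", 267.1703, 4.8)]


@dataclass
class GroundTruth:
    """Planted structure of one synthetic cohort, for scoring recovery."""

    true_random_slopes: dict[str, float] = field(default_factory=dict)
    true_random_intercepts: dict[str, float] = field(default_factory=dict)
    resilience_feature_ids: list[str] = field(default_factory=list)
    resilience_feature_signs: dict[str, int] = field(default_factory=dict)
    age_feature_ids: list[str] = field(default_factory=list)
    age_feature_signs: dict[str, int] = field(default_factory=dict)
    contaminant_feature_ids: list[str] = field(default_factory=list)
    early_rt_feature_ids: list[str] = field(default_factory=list)
    planted_spectrum_labels: dict[str, str] = field(default_factory=dict)
    parent_drugs: dict[str, dict] = field(default_factory=dict)

    def validate_against(self, table: FeatureTable | None = None,
                         spectra: list[SpectrumRecord] | None = None) -> None:
        for fid, s in {**self.resilience_feature_signs,
                       **self.age_feature_signs}.items():
            if s not in (1, -1):
                raise ValueError(f"sign for '{fid}' must be +1 or -1")
        if table is not None:
            ids = set(table.feature_ids)
            planted = (set(self.resilience_feature_ids) | set(self.age_feature_ids)
                       | set(self.contaminant_feature_ids))
            missing = planted - ids
            if missing:
                raise ValueError(f"planted features absent from table: {sorted(missing)[:5]}")
        if spectra is not None:
            sids = {s.spectrum_id for s in spectra}
            missing = set(self.planted_spectrum_labels) - sids
            if missing:
                raise ValueError(f"labeled spectra missing: {sorted(missing)[:5]}")


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate longitudinal composite cognitive z-scores.

    Returns a long-format record frame (participant_id, visit, age, sex,
    education, z) and the :class:`GroundTruth` carrying each participant's
    true random-slope deviation in SD-units per decade.
    """
    rng = _rng(config, 0)
    n, v = config.n_participants, config.n_visits
    pids = [f"P{i:04d}" for i in range(n)]

    baseline_age = rng.normal(config.baseline_age_mean, config.baseline_age_sd, n)
    female = rng.random(n) < config.female_fraction
    education = np.clip(np.round(rng.normal(14, 3, n)), 8, 20)

    cov = np.array([
        [config.intercept_sd ** 2,
         config.slope_intercept_corr * config.intercept_sd * config.slope_sd],
        [config.slope_intercept_corr * config.intercept_sd * config.slope_sd,
         config.slope_sd ** 2],
    ])
    re = rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
    b0, b1 = re[:, 0], re[:, 1]

    rows = []
    for i, pid in enumerate(pids):
        for j in range(v):
            age = baseline_age[i] + j * config.visit_spacing
            dec = (age - 70.0) / 10.0
            z = (config.population_slope * dec
                 + config.sex_effect * float(female[i])
                 + config.education_effect * (education[i] - 12.0)
                 + b0[i] + b1[i] * dec
                 + rng.normal(0.0, config.resid_sd))
            rows.append((pid, j + 1, age, "female" if female[i] else "male",
                         education[i], z))
    records = pd.DataFrame(rows, columns=["participant_id", "visit", "age",
                                          "sex", "education", "z"])
    truth = GroundTruth(
        true_random_slopes={p: float(s) for p, s in zip(pids, b1)},
        true_random_intercepts={p: float(s) for p, s in zip(pids, b0)},
    )
    return records, truth


def _sample_frame(records: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    meta = records.copy()
    meta["sample_id"] = [f"S_{p}_V{v}" for p, v in
                         zip(meta["participant_id"], meta["visit"])]
    meta["is_blank"] = False
    blanks = pd.DataFrame({
        "participant_id": [None] * config.n_blanks,
        "visit": [None] * config.n_blanks,
        "age": [np.nan] * config.n_blanks,
        "sex": [None] * config.n_blanks,
        "education": [np.nan] * config.n_blanks,
        "z": [np.nan] * config.n_blanks,
        "sample_id": [f"BLANK{i + 1:02d}" for i in range(config.n_blanks)],
        "is_blank": [True] * config.n_blanks,
    })
    return pd.concat([meta, blanks], ignore_index=True)


def generate_feature_table(config: GeneratorConfig, truth: GroundTruth,
                           records: pd.DataFrame,
                           ) -> tuple[FeatureTable, pd.DataFrame]:
    """Simulate the peak-area matrix and its sample metadata.

    Abundances are log-normal per feature; planted resilience features add
    ``sign * effect_size_resilience * b1`` (b1 = the participant's true
    slope deviation) to the log-abundance, planted age features add
    ``sign * effect_size_age * (age - 70)`` within person.  Areas below
    ``detection_limit`` are recorded as 0.  Blank channels sit at
    ``blank_level`` except for contaminant features, which dominate blanks.
    """
    rng = _rng(config, 1)
    meta = _sample_frame(records, config)
    sample_ids = meta["sample_id"].tolist()
    is_blank = meta["is_blank"].to_numpy(bool)
    p = config.n_features
    fids = [f"F{i + 1:05d}" for i in range(p)]

    # feature physical properties
    mz = rng.uniform(config.mz_min, config.mz_max, p)
    n_early = int(round(config.early_rt_fraction * p))
    rt = rng.uniform(0.7, config.rt_max, p)
    early_idx = rng.choice(p, size=n_early, replace=False)
    rt[early_idx] = rng.uniform(0.05, 0.65, n_early)

    # planted roles, drawn from non-early features so filters don't collide
    eligible = np.setdiff1d(np.arange(p), early_idx)
    rng.shuffle(eligible)
    k_res, k_age, k_con = (config.n_resilience_features, config.n_age_features,
                           config.n_contaminants)
    res_idx = eligible[:k_res]
    age_idx = eligible[k_res:k_res + k_age]
    con_idx = eligible[k_res + k_age:k_res + k_age + k_con]
    res_signs = rng.choice([-1, 1], size=k_res)
    age_signs = rng.choice([-1, 1], size=k_age)

    mu = rng.uniform(config.feature_log_mean_low, config.feature_log_mean_high, p)
    ages = meta["age"].to_numpy(float)
    b1 = np.array([truth.true_random_slopes.get(pid, 0.0) if pid is not None else 0.0
                   for pid in meta["participant_id"]])

    loga = mu[:, None] + rng.normal(0.0, config.feature_log_sd, (p, len(sample_ids)))
    for sgn, i in zip(res_signs, res_idx):
        loga[i, ~is_blank] += sgn * config.effect_size_resilience * b1[~is_blank]
    for sgn, i in zip(age_signs, age_idx):
        loga[i, ~is_blank] += sgn * config.effect_size_age * (ages[~is_blank] - 70.0)

    areas = np.exp(loga)
    # blanks: background at blank_level; contaminants dominate blanks
    if is_blank.any():
        nb = int(is_blank.sum())
        areas[:, is_blank] = config.blank_level * np.exp(
            rng.normal(0.0, 0.3, (p, nb)))
        for i in con_idx:
            areas[i, is_blank] = 20 * config.detection_limit * np.exp(
                rng.normal(0.0, 0.2, nb))
            # real-sample level of contaminants barely above detection
            areas[i, ~is_blank] = 1.5 * config.detection_limit * np.exp(
                rng.normal(0.0, 0.2, int((~is_blank).sum())))
    areas[areas < config.detection_limit] = 0.0

    features = pd.DataFrame({"mz": mz, "rt": rt}, index=pd.Index(fids, name="feature_id"))
    table = FeatureTable(features, pd.DataFrame(areas, index=features.index,
                                                columns=sample_ids))

    truth.resilience_feature_ids = [fids[i] for i in res_idx]
    truth.resilience_feature_signs = {fids[i]: int(s) for i, s in zip(res_idx, res_signs)}
    truth.age_feature_ids = [fids[i] for i in age_idx]
    truth.age_feature_signs = {fids[i]: int(s) for i, s in zip(age_idx, age_signs)}
    truth.contaminant_feature_ids = [fids[i] for i in con_idx]
    truth.early_rt_feature_ids = [fids[i] for i in sorted(early_idx)]

    meta_out = meta[["sample_id", "participant_id", "visit", "age", "sex",
                     "education", "z", "is_blank"]].rename(columns={"z": "resilience"})
    # the metadata 'resilience' column downstream carries scores, not z; leave
    # NaN here — the pipeline fills it after fitting the trajectory model
    meta_out = meta_out.assign(resilience=np.nan)
    return table, meta_out


def _noise(rng: np.random.Generator, config: GeneratorConfig) -> float:
    return float(rng.normal(0.0, config.fragment_noise_sd))


def _random_peaks(rng: np.random.Generator, precursor: float, n: int) -> list[tuple[float, float]]:
    mzs = rng.uniform(50.0, max(60.0, precursor - 20.0), n)
    return [(float(m), float(rng.uniform(5, 50))) for m in mzs]


def generate_spectra(config: GeneratorConfig, truth: GroundTruth,
                     table: FeatureTable, metadata: pd.DataFrame,
                     ) -> list[SpectrumRecord]:
    """Simulate the MS/MS spectrum set with planted query targets.

    Labels written into ``truth.planted_spectrum_labels``:
    ``glucuronide``, ``parent_drug``, ``drug_metabolite:<modification>``,
    and ``distractor:<violated property>``.
    """
    rng = _rng(config, 2)
    mods = default_modification_table()
    samples = metadata.loc[~metadata["is_blank"].astype(bool), "sample_id"].tolist()
    spectra: list[SpectrumRecord] = []
    labels: dict[str, str] = {}
    real_fids = list(table.feature_ids)

    def occ_subset(pool: list[str], frac: float) -> frozenset[str]:
        k = max(2, int(round(frac * len(pool))))
        return frozenset(rng.choice(pool, size=min(k, len(pool)), replace=False))

    # --- glucuronide conjugates -------------------------------------------
    for g in range(config.n_glucuronides):
        prec = float(rng.uniform(300, 900))
        peaks = [(prec - GLUCURONIDE_LOSS + _noise(rng, config), float(rng.uniform(40, 100)))]
        if g % 2 == 0:  # half also lose the hydrated moiety
            peaks.append((prec - WATER_GLUCURONIDE_LOSS + _noise(rng, config),
                          float(rng.uniform(20, 80))))
        peaks += _random_peaks(rng, prec, 4)
        sid = f"spec_gluc{g + 1:02d}"
        spectra.append(SpectrumRecord(
            sid, prec, float(rng.uniform(1.0, 10.0)), np.array(peaks),
            occ_subset(samples, 0.3),
            feature_id=real_fids[g % len(real_fids)]))
        labels[sid] = "glucuronide"

    # wrong-loss distractors: a single non-glucuronide loss
    for d in range(max(2, config.n_glucuronides // 4)):
        prec = float(rng.uniform(300, 900))
        peaks = [(prec - 150.0532 + _noise(rng, config), float(rng.uniform(40, 100)))]
        peaks += _random_peaks(rng, prec, 4)
        sid = f"spec_wrongloss{d + 1:02d}"
        spectra.append(SpectrumRecord(sid, prec, float(rng.uniform(1.0, 10.0)),
                                      np.array(peaks), occ_subset(samples, 0.3)))
        labels[sid] = "distractor:wrong_loss"

    # --- parent drugs and their metabolites --------------------------------
    mod_cycle = ["glucuronidation", "hydroxylation", "demethylation",
                 "glucuronidation+hydroxylation"]
    for pid, prec, prt in PARENT_DRUGS:
        parent_occ = occ_subset(samples, 0.4)
        peaks = [(m + _noise(rng, config), float(rng.uniform(50, 100)))
                 for m in BACKBONE_FRAGMENTS]
        peaks += _random_peaks(rng, prec, 3)
        spectra.append(SpectrumRecord(pid, prec, prt, np.array(peaks), parent_occ))
        labels[pid] = "parent_drug"
        truth.parent_drugs[pid] = {"precursor_mz": prec, "rt": prt,
                                   "occurrences": sorted(parent_occ)}

        pool = sorted(parent_occ)
        for m in range(config.n_metabolites_per_parent):
            mod = mod_cycle[m % len(mod_cycle)]
            delta = mods[mod]
            mprec = prec + delta + _noise(rng, config)
            n_frag = int(rng.integers(config.n_shared_fragments,
                                      len(BACKBONE_FRAGMENTS) + 1))
            frag_idx = rng.choice(len(BACKBONE_FRAGMENTS), size=n_frag, replace=False)
            peaks = [(BACKBONE_FRAGMENTS[i] + _noise(rng, config),
                      float(rng.uniform(30, 90))) for i in frag_idx]
            peaks += _random_peaks(rng, mprec, 2)
            occ = frozenset(rng.choice(pool, size=max(2, len(pool) // 2), replace=False))
            sid = f"{pid}_metab{m + 1}"
            spectra.append(SpectrumRecord(
                sid, mprec, prt - float(rng.uniform(0.5, 2.0)), np.array(peaks), occ))
            labels[sid] = f"drug_metabolite:{mod}"

        # distractors, one violated property each
        others = sorted(set(samples) - parent_occ)
        mk = lambda n: [(BACKBONE_FRAGMENTS[i] + _noise(rng, config),
                         float(rng.uniform(30, 90))) for i in range(n)]
        # (a) too few backbone fragments
        sid = f"{pid}_d_fragpoor"
        spectra.append(SpectrumRecord(
            sid, prec + mods["hydroxylation"] + _noise(rng, config),
            prt - 1.0, np.array(mk(config.n_shared_fragments - 1)
                                + _random_peaks(rng, prec, 3)),
            frozenset(pool[:3])))
        labels[sid] = "distractor:missing_fragments"
        # (b) later retention time
        sid = f"{pid}_d_latert"
        spectra.append(SpectrumRecord(
            sid, prec + mods["demethylation"] + _noise(rng, config),
            prt + 1.5, np.array(mk(config.n_shared_fragments)
                                + _random_peaks(rng, prec, 2)),
            frozenset(pool[:3])))
        labels[sid] = "distractor:later_rt"
        # (c) no co-occurrence with the parent
        if others:
            sid = f"{pid}_d_nocooc"
            spectra.append(SpectrumRecord(
                sid, prec + mods["glucuronidation"] + _noise(rng, config),
                prt - 1.2, np.array(mk(config.n_shared_fragments)
                                    + _random_peaks(rng, prec, 2)),
                frozenset(others[:max(2, len(others) // 3)])))
            labels[sid] = "distractor:no_cooccurrence"

    truth.planted_spectrum_labels = labels
    truth.validate_against(spectra=spectra)
    return spectra


def generate_all(config: GeneratorConfig,
                 ) -> tuple[pd.DataFrame, FeatureTable, pd.DataFrame,
                            list[SpectrumRecord], GroundTruth]:
    """Cohort + feature table + metadata + spectra in one call."""
    records, truth = generate_cohort(config)
    table, meta = generate_feature_table(config, truth, records)
    spectra = generate_spectra(config, truth, table, meta)
    truth.validate_against(table=table, spectra=spectra)
    return records, table, meta, spectra, truth
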