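"""Containers and readers/writers for the formats the pipeline touches.

Feature quantification tables and sample metadata travel as CSV, MS/MS
spectra as Mascot Generic Format (MGF, via :mod:`pyteomics.mgf`), and
ground-truth / config echoes as JSON.  Retention time is minutes
internally; MGF ``RTINSECONDS`` is converted on read.  A peak area of 0
means "not detected" — tables on disk carry no NaNs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

__all__ = [
    "FeatureTable", "SpectrumRecord", "ParseError",
    "read_feature_table", "write_feature_table",
    "read_metadata", "write_metadata", "validate_metadata",
    "read_mgf", "write_mgf",
    "read_truth_json", "write_truth_json",
    "setup_logging",
]

log = logging.getLogger("resilmet")

METADATA_COLUMNS = [
    "sample_id", "participant_id", "visit", "age", "sex", "education",
    "resilience", "is_blank",
]


class ParseError(ValueError):
    """A file failed validation; the message names the offending location."""


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """An untargeted LC-MS feature table: features x samples peak areas.

    ``features`` is indexed by feature_id with columns ``mz`` (Da) and
    ``rt`` (minutes); ``areas`` shares that index and has one column per
    sample.  Zero area encodes "not detected".
    """

    features: pd.DataFrame   # index feature_id; columns mz, rt
    areas: pd.DataFrame      # index feature_id; columns sample_id

    def __post_init__(self) -> None:
        self.validate()

    @property
    def feature_ids(self) -> pd.Index:
        return self.features.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.areas.columns

    @property
    def mz(self) -> pd.Series:
        return self.features["mz"]

    @property
    def rt(self) -> pd.Series:
        return self.features["rt"]

    @property
    def shape(self) -> tuple[int, int]:
        return self.areas.shape

    def validate(self) -> None:
        if not self.features.index.equals(self.areas.index):
            raise ParseError("feature metadata and area matrix indices differ")
        if self.features.index.has_duplicates:
            dup = self.features.index[self.features.index.duplicated()][0]
            raise ParseError(f"duplicate feature_id '{dup}'")
        if self.areas.columns.has_duplicates:
            dup = self.areas.columns[self.areas.columns.duplicated()][0]
            raise ParseError(f"duplicate sample_id '{dup}'")
        vals = self.areas.to_numpy()
        if np.isnan(vals).any():
            i, j = np.argwhere(np.isnan(vals))[0]
            raise ParseError(
                f"NaN area at feature '{self.feature_ids[i]}', "
                f"sample '{self.sample_ids[j]}'"
            )
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ParseError(
                f"negative area at feature '{self.feature_ids[i]}', "
                f"sample '{self.sample_ids[j]}'"
            )
        mz = self.features["mz"].to_numpy(float)
        if ((mz <= 0) | (mz >= 5000)).any():
            bad = self.features.index[(mz <= 0) | (mz >= 5000)][0]
            raise ParseError(f"m/z out of (0, 5000) for feature '{bad}'")
        rt = self.features["rt"].to_numpy(float)
        if (rt < 0).any():
            bad = self.features.index[rt < 0][0]
            raise ParseError(f"negative retention time for feature '{bad}'")

    def subset_features(self, keep: Sequence[str] | pd.Index) -> "FeatureTable":
        keep = pd.Index(keep)
        return FeatureTable(self.features.loc[keep].copy(), self.areas.loc[keep].copy())

    def subset_samples(self, keep: Sequence[str] | pd.Index) -> "FeatureTable":
        keep = pd.Index(keep)
        return FeatureTable(self.features.copy(), self.areas.loc[:, keep].copy())

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.areas.copy())


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = pd.concat([table.features[["mz", "rt"]], table.areas], axis=1)
    df.index.name = "feature_id"
    df.to_csv(path, float_format="%.10g")


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path)
    for col in ("feature_id", "mz", "rt"):
        if col not in df.columns:
            raise ParseError(f"feature table {path}: missing column '{col}'")
    df = df.set_index("feature_id")
    sample_cols = [c for c in df.columns if c not in ("mz", "rt")]
    if not sample_cols:
        raise ParseError(f"feature table {path}: no sample columns")
    areas = df[sample_cols].astype(float)
    return FeatureTable(df[["mz", "rt"]].astype(float), areas)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-metadata contract and return the frame.

    Non-blank samples must map to a participant; blanks must not.
    (participant, visit) pairs are unique among non-blank samples.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"sample metadata: missing columns {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"sample metadata: duplicate sample_id '{dup}'")
    blanks = meta["is_blank"].astype(bool)
    nb = meta.loc[~blanks]
    if nb["participant_id"].isna().any():
        bad = nb.loc[nb["participant_id"].isna(), "sample_id"].iloc[0]
        raise ParseError(f"non-blank sample '{bad}' has no participant_id")
    pv = nb[["participant_id", "visit"]]
    if pv.duplicated().any():
        bad = pv.loc[pv.duplicated()].iloc[0]
        raise ParseError(
            f"duplicate (participant, visit) pair "
            f"({bad['participant_id']}, {bad['visit']})"
        )
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(meta).to_csv(path, index=False, float_format="%.10g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    meta["is_blank"] = meta["is_blank"].astype(bool)
    return validate_metadata(meta)


# ---------------------------------------------------------------------------
# MS/MS spectra (MGF)
# ---------------------------------------------------------------------------

@dataclass
class SpectrumRecord:
    """One tandem mass spectrum with its sample-occurrence list.

    Peaks are stored sorted by fragment m/z.  ``sample_occurrences`` lists
    the samples in which the corresponding LC-MS feature was detected; it
    round-trips through a ``samples=`` token embedded in the MGF TITLE.
    """

    spectrum_id: str
    precursor_mz: float
    rt: float                                  # minutes
    peaks: np.ndarray                          # (n, 2): m/z, intensity
    sample_occurrences: frozenset[str] = frozenset()
    feature_id: str | None = None

    def __post_init__(self) -> None:
        pk = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        pk = pk[np.argsort(pk[:, 0], kind="stable")]
        if (pk[:, 1] < 0).any():
            raise ParseError(f"spectrum '{self.spectrum_id}': negative intensity")
        if pk.size and pk[-1, 0] >= self.precursor_mz + 1.0:
            raise ParseError(
                f"spectrum '{self.spectrum_id}': fragment m/z {pk[-1, 0]:.4f} "
                f"exceeds precursor + 1.0"
            )
        self.peaks = pk
        self.sample_occurrences = frozenset(self.sample_occurrences)

    @property
    def fragment_mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensities(self) -> np.ndarray:
        return self.peaks[:, 1]


def write_mgf(spectra: Iterable[SpectrumRecord], path: str | Path) -> None:
    entries = []
    for s in spectra:
        title = f"{s.spectrum_id}"
        if s.feature_id is not None:
            title += f" feature={s.feature_id}"
        if s.sample_occurrences:
            title += " samples=" + ";".join(sorted(s.sample_occurrences))
        entries.append({
            "m/z array": s.peaks[:, 0],
            "intensity array": s.peaks[:, 1],
            "params": {
                "title": title,
                "pepmass": s.precursor_mz,
                "rtinseconds": s.rt * 60.0,
            },
        })
    _mgf.write(entries, str(path), fragment_format="%.6f %.6f", write_charges=False,
               file_mode="w")


def _mgf_error_line(path: Path) -> str:
    """Best-effort location of the first malformed line, for error messages."""
    in_block = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            t = line.strip()
            if t == "BEGIN IONS":
                in_block = True
                continue
            if t == "END IONS":
                in_block = False
                continue
            if in_block and t and "=" not in t:
                parts = t.split()
                try:
                    [float(x) for x in parts[:2]]
                except ValueError:
                    return f" (line {lineno}: '{t}')"
    if in_block:
        return " (unterminated BEGIN IONS block)"
    return ""


def read_mgf(path: str | Path) -> list[SpectrumRecord]:
    path = Path(path)
    out: list[SpectrumRecord] = []
    try:
        with _mgf.read(str(path), convert_arrays=1, use_index=False) as reader:
            for entry in reader:
                params = entry["params"]
                title = str(params.get("title", f"spectrum{len(out)}"))
                tokens = title.split()
                sid = tokens[0] if tokens else f"spectrum{len(out)}"
                feature_id = None
                occ: frozenset[str] = frozenset()
                for tok in tokens[1:]:
                    if tok.startswith("feature="):
                        feature_id = tok[len("feature="):]
                    elif tok.startswith("samples="):
                        occ = frozenset(x for x in tok[len("samples="):].split(";") if x)
                pepmass = params.get("pepmass")
                if pepmass is None:
                    raise ParseError(f"{path}: spectrum '{sid}' lacks PEPMASS")
                prec = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
                rt_s = params.get("rtinseconds", 0.0)
                peaks = np.column_stack([entry["m/z array"], entry["intensity array"]])
                out.append(SpectrumRecord(
                    spectrum_id=sid, precursor_mz=prec, rt=float(rt_s) / 60.0,
                    peaks=peaks, sample_occurrences=occ, feature_id=feature_id,
                ))
    except ParseError:
        raise
    except Exception as exc:  # pyteomics raises assorted errors; add location
        raise ParseError(f"malformed MGF {path}{_mgf_error_line(path)}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# JSON sidecars
# ---------------------------------------------------------------------------

def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_truth_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonify)


def read_truth_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
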