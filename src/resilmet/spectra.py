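"""MS/MS query operators: neutral-loss, shared-fragment, co-occurrence,
retention-time precedence, and delta-mass annotation.

These reproduce the discovery logic used to pull glucuronide conjugates
and β-blocker (metoprolol / atenolol) metabolites out of an untargeted
MS/MS collection:

* a **neutral-loss query** flags spectra with a fragment sitting a fixed
  mass below the precursor (glucuronic-acid cleavage loses C6H8O6 =
  176.0321 Da, or 194.0425 Da with water);
* a **fragment-set query** flags spectra sharing the aryloxypropanolamine
  backbone ions (m/z 72.0806, 98.0964, 116.1070, 133.0643);
* metabolite candidates are then required to **co-occur** with their
  parent drug in at least one sample, to elute **earlier** than the
  parent, and are annotated by the **delta mass** between their precursor
  and the parent's (glucuronidation +176.0321, hydroxylation +15.9949,
  demethylation −14.0157, and pairwise combinations).

Matching is presence-based: intensities are ignored except for an
optional relative-intensity floor.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import SpectrumRecord

__all__ = [
    "ELEMENT_MASSES", "BACKBONE_FRAGMENTS", "GLUCURONIDE_LOSS",
    "WATER_GLUCURONIDE_LOSS", "GLUCURONIDE_LOSSES",
    "monoisotopic_mass", "default_modification_table", "ParentDrug",
    "QueryMatch", "neutral_loss_query", "fragment_set_query",
    "cooccurrence_filter", "rt_precedence_check", "delta_mass_annotate",
    "assign_parents", "drug_metabolite_pipeline",
]

#: monoisotopic element masses, Da (carbon-12 scale; C exactly 12)
ELEMENT_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "P": 30.97376200,
}

#: shared aryloxypropanolamine backbone fragment ions of β-blockers, m/z
BACKBONE_FRAGMENTS: tuple[float, ...] = (72.0806, 98.0964, 116.1070, 133.0643)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of an elemental formula such as ``"C6H8O6"``."""
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ValueError(f"malformed formula: '{formula}'")
    total = 0.0
    for sym, count in _FORMULA_TOKEN.findall(formula):
        if sym not in ELEMENT_MASSES:
            raise ValueError(f"unknown element '{sym}' in formula '{formula}'")
        total += ELEMENT_MASSES[sym] * (int(count) if count else 1)
    return total


#: neutral loss of a glucuronic-acid moiety (C6H8O6)
GLUCURONIDE_LOSS: float = 176.0321
#: glucuronide loss retaining water, as conventionally quoted
WATER_GLUCURONIDE_LOSS: float = 194.0425
GLUCURONIDE_LOSSES: tuple[float, float] = (GLUCURONIDE_LOSS, WATER_GLUCURONIDE_LOSS)

#: phase-I/II biotransformation building blocks: name -> (formula, sign)
_BASE_MODIFICATIONS: dict[str, tuple[str, int]] = {
    "glucuronidation": ("C6H8O6", +1),
    "hydroxylation": ("O", +1),
    "demethylation": ("CH2", -1),
}


def default_modification_table(combinations: bool = True) -> dict[str, float]:
    """Delta masses (Da) of common drug biotransformations.

    Every entry is derived from :data:`ELEMENT_MASSES` and an elemental
    composition change; with ``combinations=True`` all pairwise sums of
    the base modifications are included (e.g.
    ``hydroxylation+glucuronidation``).
    """
    table = {name: sign * monoisotopic_mass(f)
             for name, (f, sign) in _BASE_MODIFICATIONS.items()}
    if combinations:
        for (a, da), (b, db) in itertools.combinations(sorted(table.items()), 2):
            table[f"{a}+{b}"] = da + db
    return {k: round(v, 6) for k, v in table.items()}


@dataclass(frozen=True)
class ParentDrug:
    """A parent compound against which metabolite candidates are judged."""

    parent_id: str
    precursor_mz: float
    rt: float | None = None                     # minutes
    occurrences: frozenset[str] = frozenset()


@dataclass
class QueryMatch:
    """Outcome of one spectrum against one query rule."""

    spectrum_id: str
    rule: str                                   # e.g. "loss:176.0321" or "fragments:3/4"
    mass_error: float                           # Da, best matching error
    matched_values: tuple[float, ...] = ()      # losses or fragment m/z that matched
    sample_occurrences: frozenset[str] = frozenset()
    precursor_mz: float = float("nan")
    rt: float | None = None
    parent_id: str | None = None
    parent_ambiguous: bool = False
    delta_mass: float | None = None
    co_occurrence_ok: bool | None = None
    rt_precedence_ok: bool | None = None
    annotation: str | None = None
    annotation_candidates: list[tuple[str, float]] = field(default_factory=list)


def _match_from(spectrum: SpectrumRecord, rule: str, err: float,
                matched: Sequence[float]) -> QueryMatch:
    return QueryMatch(
        spectrum_id=spectrum.spectrum_id, rule=rule, mass_error=err,
        matched_values=tuple(matched),
        sample_occurrences=spectrum.sample_occurrences,
        precursor_mz=spectrum.precursor_mz, rt=spectrum.rt,
    )


def _usable_peaks(spectrum: SpectrumRecord, min_rel_intensity: float) -> np.ndarray:
    mz = spectrum.fragment_mz
    if min_rel_intensity > 0 and len(mz):
        top = spectrum.intensities.max()
        mz = mz[spectrum.intensities >= min_rel_intensity * top]
    return mz


def neutral_loss_query(spectra: Iterable[SpectrumRecord],
                       losses: Sequence[float] = GLUCURONIDE_LOSSES,
                       tol: float = 0.01,
                       min_rel_intensity: float = 0.0) -> list[QueryMatch]:
    """Spectra with a fragment a fixed neutral loss below the precursor.

    A spectrum matches if for some loss L there is a fragment f with
    ``|precursor − f − L| ≤ tol``; every qualifying loss is reported in
    ``matched_values`` and the smallest absolute error in ``mass_error``.
    """
    losses = list(losses)
    if not losses:
        raise ValueError("neutral_loss_query: empty loss list")
    out: list[QueryMatch] = []
    for s in spectra:
        mz = _usable_peaks(s, min_rel_intensity)
        if not len(mz):
            continue
        observed_losses = s.precursor_mz - mz
        hits, best = [], np.inf
        for L in losses:
            err = np.abs(observed_losses - L).min()
            if err <= tol:
                hits.append(L)
                best = min(best, float(err))
        if hits:
            m = _match_from(s, f"loss:{'|'.join(f'{L:.4f}' for L in hits)}", best, hits)
            out.append(m)
    return out


def fragment_set_query(spectra: Iterable[SpectrumRecord],
                       fragments: Sequence[float] = BACKBONE_FRAGMENTS,
                       tol: float = 0.01, min_matched: int = 3,
                       min_rel_intensity: float = 0.0) -> list[QueryMatch]:
    """Spectra carrying at least ``min_matched`` of the query fragment ions."""
    fragments = list(fragments)
    if not fragments:
        raise ValueError("fragment_set_query: empty fragment list")
    if not 1 <= min_matched <= len(fragments):
        raise ValueError("fragment_set_query: min_matched out of range")
    out: list[QueryMatch] = []
    for s in spectra:
        mz = _usable_peaks(s, min_rel_intensity)
        if not len(mz):
            continue
        matched, errs = [], []
        for f in fragments:
            err = np.abs(mz - f).min()
            if err <= tol:
                matched.append(f)
                errs.append(float(err))
        if len(matched) >= min_matched:
            out.append(_match_from(
                s, f"fragments:{len(matched)}/{len(fragments)}",
                min(errs), matched))
    return out


def assign_parents(matches: Iterable[QueryMatch], parents: Sequence[ParentDrug],
                   mods: Mapping[str, float] | None = None,
                   tol: float = 0.01) -> list[QueryMatch]:
    """Attach each match to its nearest-delta-mass parent.

    For every parent the precursor delta Δ is scored by the distance to
    the closest known modification delta; the parent with the smallest
    score wins (ties flagged ambiguous).  A |Δ| ≤ tol to some parent marks
    the spectrum as that parent itself (``annotation='parent'``).
    """
    if not parents:
        raise ValueError("assign_parents: no parents given")
    mods = dict(mods) if mods is not None else default_modification_table()
    mod_deltas = np.array(list(mods.values()))
    out = []
    for m in matches:
        deltas = {p.parent_id: m.precursor_mz - p.precursor_mz for p in parents}
        self_hits = [pid for pid, d in deltas.items() if abs(d) <= tol]
        if self_hits:
            m.parent_id = self_hits[0]
            m.delta_mass = deltas[self_hits[0]]
            m.annotation = "parent"
            out.append(m)
            continue
        scores = {pid: float(np.abs(mod_deltas - d).min()) for pid, d in deltas.items()}
        best = min(scores, key=lambda k: (scores[k], k))
        ties = [pid for pid, sc in scores.items()
                if pid != best and abs(sc - scores[best]) <= 1e-9]
        m.parent_id = best
        m.parent_ambiguous = bool(ties)
        m.delta_mass = deltas[best]
        out.append(m)
    return out


def cooccurrence_filter(matches: Iterable[QueryMatch],
                        parents: Sequence[ParentDrug],
                        drop: bool = True) -> list[QueryMatch]:
    """Keep matches whose samples intersect their assigned parent's samples.

    Matches must have been through :func:`assign_parents`.  A match with
    an empty occurrence set is flagged not-retained.
    """
    by_id = {p.parent_id: p for p in parents}
    out = []
    for m in matches:
        if m.parent_id is None:
            raise ValueError(f"match '{m.spectrum_id}' has no assigned parent")
        parent = by_id[m.parent_id]
        ok = bool(m.sample_occurrences) and bool(
            m.sample_occurrences & parent.occurrences)
        m.co_occurrence_ok = ok
        if ok or not drop:
            out.append(m)
    return out


def rt_precedence_check(matches: Iterable[QueryMatch],
                        parents: Sequence[ParentDrug] | float) -> list[QueryMatch]:
    """Flag whether each candidate elutes strictly before its parent.

    ``parents`` may be a single parent RT (minutes) applied to all
    matches, or the parent list (RT looked up via ``parent_id``).
    Equal RT fails; a missing RT leaves the flag ``None`` (indeterminate).
    """
    if isinstance(parents, (int, float)):
        rt_of = lambda m: float(parents)
    else:
        by_id = {p.parent_id: p.rt for p in parents}
        rt_of = lambda m: by_id.get(m.parent_id)
    out = []
    for m in matches:
        prt = rt_of(m)
        if prt is None or m.rt is None:
            m.rt_precedence_ok = None
        else:
            m.rt_precedence_ok = m.rt < prt
        out.append(m)
    return out


def delta_mass_annotate(matches: Iterable[QueryMatch],
                        parent_mz: float | Sequence[ParentDrug] | None = None,
                        mods: Mapping[str, float] | None = None,
                        tol: float = 0.01) -> list[QueryMatch]:
    """Annotate candidates by the precursor mass shift from their parent.

    The shift Δ is matched against the modification table; all candidates
    within ``tol`` are reported sorted by absolute error, the best one
    becoming ``annotation``.  An unexplained Δ is labeled by its bare
    value (e.g. ``"Δm=+21.9819"``).
    """
    mods = dict(mods) if mods is not None else default_modification_table()
    if parent_mz is None:
        mz_of = lambda m: None
    elif isinstance(parent_mz, (int, float)):
        mz_of = lambda m: float(parent_mz)
    else:
        by_id = {p.parent_id: p.precursor_mz for p in parent_mz}
        mz_of = lambda m: by_id.get(m.parent_id)
    out = []
    for m in matches:
        if m.annotation == "parent":
            out.append(m)
            continue
        pmz = mz_of(m)
        delta = (m.precursor_mz - pmz) if pmz is not None else m.delta_mass
        if delta is None:
            raise ValueError(f"match '{m.spectrum_id}': parent m/z unknown")
        m.delta_mass = float(delta)
        cands = sorted(
            ((name, abs(delta - d)) for name, d in mods.items() if abs(delta - d) <= tol),
            key=lambda t: t[1])
        m.annotation_candidates = [(n, float(e)) for n, e in cands]
        m.annotation = cands[0][0] if cands else f"Δm={delta:+.4f}"
        out.append(m)
    return out


def drug_metabolite_pipeline(spectra: Iterable[SpectrumRecord],
                             parents: Sequence[ParentDrug],
                             fragments: Sequence[float] = BACKBONE_FRAGMENTS,
                             mods: Mapping[str, float] | None = None,
                             tol: float = 0.01, min_matched: int = 3,
                             ) -> list[QueryMatch]:
    """Composed metabolite discovery: fragment set → parent assignment →
    co-occurrence → RT precedence → delta-mass annotation.

    Returns annotated candidates that carry the backbone, co-occur with
    their parent, and elute before it; the parent spectra themselves are
    excluded.
    """
    matches = fragment_set_query(spectra, fragments, tol=tol, min_matched=min_matched)
    matches = assign_parents(matches, parents, mods=mods, tol=tol)
    matches = [m for m in matches if m.annotation != "parent"]
    matches = cooccurrence_filter(matches, parents, drop=True)
    matches = rt_precedence_check(matches, parents)
    matches = [m for m in matches if m.rt_precedence_ok]
    return delta_mass_annotate(matches, parents, mods=mods, tol=tol)
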