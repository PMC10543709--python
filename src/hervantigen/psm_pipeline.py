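"""Peptide-level validation of search-engine PSM lists.

Raw peptide-spectrum matches (targets and decoys from a concatenated
target-decoy search) are collapsed to peptides (best score per distinct
peptide/decoy-status), assigned q-values with the simple concatenated-TDC
estimator ``FDR(t) = #decoys>=t / #targets>=t``, filtered at the detection
threshold (q <= 0.01, lengths 8-12 by default), and annotated:

* novelty against canonical proteomes, robust to the Leu/Ile isobaric
  ambiguity of mass spectrometry (L/I-expanded substring search);
* database category by precedence canonical > mutanome > herv_orf;
* source-hERV disambiguation by highest expression in the sample.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .search_db import (
    CATEGORIES,
    CATEGORY_CANONICAL,
    CATEGORY_HERV_ORF,
    CATEGORY_MUTANOME,
    HervTranscript,
    SearchDbEntry,
)

#: combinatorial L/I expansion is capped at this many ambiguous sites
MAX_LI_SITES = 12


@dataclass(frozen=True)
class PsmRecord:
    peptide: str
    score: float
    is_decoy: bool
    sample: str
    charge: int = 2
    modifications: str = ""

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("empty peptide")
        if not np.isfinite(self.score):
            raise ValueError("PSM score must be finite")


@dataclass(frozen=True)
class CollapsedPeptide:
    peptide: str
    best_score: float
    is_decoy: bool
    samples: frozenset[str]


@dataclass
class PeptideIdentification:
    peptide: str
    best_score: float
    q_value: float
    samples_detected: frozenset[str]
    category: str | None = None
    source_ids: tuple[str, ...] = ()
    source_assigned: str | None = None

    @property
    def length(self) -> int:
        return len(self.peptide)


def collapse_to_peptides(psms: Iterable[PsmRecord]) -> list[CollapsedPeptide]:
    """One row per distinct (peptide, decoy-status): max score, samples unioned.

    Modification strings are ignored for identity — identification is by
    peptide sequence.  A sequence observed both as target and as decoy is
    kept as two rows.
    """
    acc: dict[tuple[str, bool], tuple[float, set[str]]] = {}
    for psm in psms:
        key = (psm.peptide, psm.is_decoy)
        if key in acc:
            best, samples = acc[key]
            acc[key] = (max(best, psm.score), samples | {psm.sample})
        else:
            acc[key] = (psm.score, {psm.sample})
    return [
        CollapsedPeptide(pep, best, dec, frozenset(samples))
        for (pep, dec), (best, samples) in acc.items()
    ]


def compute_qvalues(
    collapsed: Sequence[CollapsedPeptide],
    plus_one: bool = False,
) -> dict[str, float]:
    """Peptide-level q-values for target peptides by concatenated TDC.

    At score threshold ``t``, ``FDR(t) = #decoys>=t / #targets>=t`` (with
    ``#decoys+1`` in the numerator when ``plus_one``); the q-value of a
    target with score ``s`` is the minimum FDR over thresholds ``t <= s``,
    capped at 1, which makes q nonincreasing in score.
    """
    targets = [c for c in collapsed if not c.is_decoy]
    if not targets:
        raise ValueError("no target peptides: empty analysis")
    decoys = [c for c in collapsed if c.is_decoy]

    t_scores = np.array([c.best_score for c in targets])
    d_scores = np.array([c.best_score for c in decoys])
    thresholds = np.unique(np.concatenate([t_scores, d_scores]))[::-1]
    # counts >= t for descending thresholds
    n_t = np.searchsorted(np.sort(t_scores), thresholds, side="left")
    n_t = len(t_scores) - n_t
    n_d = np.searchsorted(np.sort(d_scores), thresholds, side="left")
    n_d = len(d_scores) - n_d
    num = n_d + (1 if plus_one else 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_t > 0, num / np.maximum(n_t, 1), np.inf)
    # q at threshold t_j = min FDR over thresholds <= t_j (suffix of the
    # descending list); cumulative min from the smallest threshold up
    q_at = np.minimum.accumulate(fdr[::-1])[::-1]
    q_at = np.minimum(q_at, 1.0)
    idx = np.searchsorted(-thresholds, -t_scores, side="left")
    return {c.peptide: float(q_at[i]) for c, i in zip(targets, idx)}


def filter_identifications(
    collapsed: Sequence[CollapsedPeptide],
    qvalues: Mapping[str, float],
    q_max: float = 0.01,
    min_len: int = 8,
    max_len: int = 12,
) -> list[PeptideIdentification]:
    """Apply the detection threshold: targets only, q <= q_max, length in range."""
    out: list[PeptideIdentification] = []
    for c in collapsed:
        if c.is_decoy:
            continue
        q = qvalues[c.peptide]
        if q > q_max or not min_len <= len(c.peptide) <= max_len:
            continue
        out.append(PeptideIdentification(c.peptide, c.best_score, q, c.samples))
    out.sort(key=lambda i: (i.q_value, -i.best_score, i.peptide))
    return out


def expand_leu_ile(peptide: str, mode: str = "combinatorial") -> set[str]:
    """Isobaric Leu/Ile variants of ``peptide``; always contains the original.

    ``combinatorial``: all 2^k variants over the k L/I sites (k capped at
    ``MAX_LI_SITES``); ``swap_all``: the original plus the single variant
    with every L and I exchanged.
    """
    sites = [i for i, aa in enumerate(peptide) if aa in "LI"]
    if mode == "swap_all":
        swapped = "".join(
            "I" if aa == "L" else "L" if aa == "I" else aa for aa in peptide
        )
        return {peptide, swapped}
    if mode != "combinatorial":
        raise ValueError(f"unknown L/I expansion mode {mode!r}")
    if len(sites) > MAX_LI_SITES:
        raise ValueError(
            f"{len(sites)} L/I sites exceeds the combinatorial cap of {MAX_LI_SITES}"
        )
    variants: set[str] = set()
    for combo in itertools.product("LI", repeat=len(sites)):
        chars = list(peptide)
        for site, aa in zip(sites, combo):
            chars[site] = aa
        variants.add("".join(chars))
    return variants


def _as_blob(sequences: Iterable[str]) -> str:
    return "*" + "*".join(sequences) + "*"


def check_novelty(
    peptide: str,
    canonical_proteomes: Sequence[Iterable[str]],
    mode: str = "combinatorial",
) -> bool:
    """True iff no L/I-expanded variant occurs in any canonical proteome."""
    blobs = []
    for proteome in canonical_proteomes:
        seqs = list(proteome)
        if not seqs:
            raise ValueError("empty canonical proteome: misconfigured novelty check")
        blobs.append(_as_blob(seqs))
    if not blobs:
        raise ValueError("no canonical proteome supplied")
    for variant in expand_leu_ile(peptide, mode):
        for blob in blobs:
            if variant in blob:
                return False
    return True


class DbIndex:
    """Substring index over a search database, grouped by category."""

    def __init__(self, entries: Sequence[SearchDbEntry]):
        self.entries = list(entries)
        self._by_cat: dict[str, list[SearchDbEntry]] = {c: [] for c in CATEGORIES}
        for e in self.entries:
            self._by_cat[e.category].append(e)
        self._blob = {
            c: _as_blob([e.sequence for e in es]) if es else ""
            for c, es in self._by_cat.items()
        }

    def contains(self, peptide: str, category: str) -> bool:
        blob = self._blob[category]
        return bool(blob) and peptide in blob

    def entries_containing(self, peptide: str, category: str) -> list[SearchDbEntry]:
        return [e for e in self._by_cat[category] if peptide in e.sequence]


def assign_category(peptide: str, db: DbIndex | Sequence[SearchDbEntry]) -> str:
    """Category by precedence canonical > mutanome > herv_orf.

    A peptide explainable by a canonical protein is never called a
    mutanome or hERV peptide.  A peptide matching no entry signals an
    identification outside the search space and raises.
    """
    if not isinstance(db, DbIndex):
        db = DbIndex(db)
    for category in (CATEGORY_CANONICAL, CATEGORY_MUTANOME, CATEGORY_HERV_ORF):
        if db.contains(peptide, category):
            return category
    raise ValueError(f"peptide {peptide} matches no search-database entry")


def assign_source_herv(
    peptide: str,
    db: DbIndex | Sequence[SearchDbEntry],
    expression: Mapping[str, Mapping[str, float]] | Sequence[HervTranscript],
    sample: str,
) -> tuple[str, tuple[str, ...]]:
    """Pick the representative source hERV for an hERV-ORF peptide.

    Among all hERVs whose ORF translations contain the peptide, the one
    with the highest TPM in ``sample`` is chosen; ties break
    lexicographically by hERV id.  Returns (assigned id, all candidates).
    """
    if not isinstance(db, DbIndex):
        db = DbIndex(db)
    if not isinstance(expression, Mapping):
        expression = {h.herv_id: h.tpm for h in expression}
    hits = db.entries_containing(peptide, CATEGORY_HERV_ORF)
    candidates = sorted({str(e.provenance["source_id"]) for e in hits})
    if not candidates:
        raise ValueError(f"peptide {peptide} occurs in no hERV ORF")
    assigned = min(
        candidates,
        key=lambda hid: (-float(expression.get(hid, {}).get(sample, 0.0)), hid),
    )
    return assigned, tuple(candidates)


def annotate_identifications(
    identifications: Sequence[PeptideIdentification],
    db: DbIndex | Sequence[SearchDbEntry],
    expression: Mapping[str, Mapping[str, float]] | Sequence[HervTranscript],
    sample: str,
) -> list[PeptideIdentification]:
    """Assign category, source ids and (for hERV peptides) the source hERV."""
    if not isinstance(db, DbIndex):
        db = DbIndex(db)
    out = []
    for ident in identifications:
        category = assign_category(ident.peptide, db)
        hits = db.entries_containing(ident.peptide, category)
        sources = tuple(sorted({str(e.provenance.get("source_id", e.entry_id)) for e in hits}))
        assigned = sources[0] if sources else None
        if category == CATEGORY_HERV_ORF:
            assigned, sources = assign_source_herv(ident.peptide, db, expression, sample)
        ident = replace(
            ident, category=category, source_ids=sources, source_assigned=assigned
        )
        out.append(ident)
    return out
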