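"""Immunopeptidome summary statistics.

Length distributions, anchor-residue position-frequency matrices with
per-position information content, HLA-binding percentile-rank summaries
through a pluggable predictor interface, the hERV fraction of the
peptidome, and source-ORF length comparisons between canonical and
hERV-derived ligands.

The built-in predictor is a position-weight scorer over an HLA-A24-like
anchor profile (Tyr/Phe at position 2; Phe/Leu/Ile at the C terminus),
percentile-calibrated per peptide length against a fixed seeded random
background, so its ranks are exchangeable with those of an external
predictor (rank < 0.5 strong binder, < 2.0 weak, else non-binder).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .psm_pipeline import PeptideIdentification
from .search_db import AA_ALPHABET, CATEGORY_HERV_ORF, SearchDbEntry

STRONG_RANK = 0.5
WEAK_RANK = 2.0

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


def round_percent(x: float, ndigits: int = 1) -> float:
    """Half-up rounding for reported percentages (e.g. 0.34755 -> 0.3)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Column-normalized residue frequencies of equal-length peptides."""

    length: int
    freq: np.ndarray  # (length, 20), columns ordered by AA_ALPHABET
    n_peptides: int

    @property
    def information_content(self) -> np.ndarray:
        """Per-position IC in bits: log2(20) minus the column entropy."""
        p = np.clip(self.freq, 1e-300, 1.0)
        entropy = -(self.freq * np.log2(p)).sum(axis=1)
        return np.log2(20.0) - entropy

    def consensus(self) -> str:
        return "".join(AA_ALPHABET[i] for i in self.freq.argmax(axis=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freq,
            index=pd.RangeIndex(1, self.length + 1, name="position"),
            columns=list(AA_ALPHABET),
        )


@dataclass(frozen=True)
class BinderPrediction:
    peptide: str
    percentile_rank: float

    @property
    def binder_class(self) -> str:
        if self.percentile_rank < STRONG_RANK:
            return "strong"
        if self.percentile_rank < WEAK_RANK:
            return "weak"
        return "non"


def length_distribution(
    identifications: Sequence[PeptideIdentification],
    by_sample: bool = False,
    lengths: range = range(8, 13),
) -> pd.DataFrame:
    """Peptide counts per length (rows), optionally split per sample (columns)."""
    if by_sample:
        samples = sorted({s for i in identifications for s in i.samples_detected})
        data = {
            s: [
                sum(1 for i in identifications if i.length == L and s in i.samples_detected)
                for L in lengths
            ]
            for s in samples
        }
    else:
        data = {"count": [sum(1 for i in identifications if i.length == L) for L in lengths]}
    return pd.DataFrame(data, index=pd.Index(list(lengths), name="length"))


def build_pfm(nine_mers: Sequence[str]) -> PositionFrequencyMatrix:
    """Position-frequency matrix of a set of equal-length (typically 9-mer) peptides."""
    if not nine_mers:
        raise ValueError("no peptides")
    length = len(nine_mers[0])
    if any(len(p) != length for p in nine_mers):
        raise ValueError("mixed peptide lengths")
    counts = np.zeros((length, len(AA_ALPHABET)))
    for pep in nine_mers:
        for pos, aa in enumerate(pep):
            counts[pos, _AA_INDEX[aa]] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)
    return PositionFrequencyMatrix(length, freq, len(nine_mers))


class PredictorError(RuntimeError):
    """Raised when a binding predictor fails; never silently skipped."""


class PositionWeightPredictor:
    """Built-in HLA-A24-like percentile-rank predictor.

    Scores a peptide as the sum of per-(position, residue) weights: a
    strong bonus for Tyr (and a weaker one for Phe) at anchor position 2,
    graded bonuses for Phe/Leu/Ile at the C terminus, and a small fixed
    jitter everywhere else so scores are effectively continuous.  The raw
    score is converted to a percentile rank in [0, 100] against a seeded
    random-peptide background per length (fraction of background peptides
    scoring strictly better), making ranks uniform on random peptides.
    """

    #: internal calibration seed — fixed so the predictor is a pure function
    CALIBRATION_SEED = 20230822
    BACKGROUND_SIZE = 100_000

    _P2_BONUS = {"Y": 4.0, "F": 1.5}
    _CTERM_BONUS = {"F": 3.0, "L": 2.7, "I": 2.4}

    @classmethod
    @lru_cache(maxsize=8)
    def _weights(cls, length: int) -> np.ndarray:
        rng = np.random.default_rng([cls.CALIBRATION_SEED, length])
        w = rng.normal(0.0, 0.05, size=(length, len(AA_ALPHABET)))
        for aa, bonus in cls._P2_BONUS.items():
            w[1, _AA_INDEX[aa]] += bonus
        for aa, bonus in cls._CTERM_BONUS.items():
            w[length - 1, _AA_INDEX[aa]] += bonus
        return w

    @classmethod
    @lru_cache(maxsize=8)
    def _background(cls, length: int) -> np.ndarray:
        rng = np.random.default_rng([cls.CALIBRATION_SEED + 1, length])
        idx = rng.integers(0, len(AA_ALPHABET), size=(cls.BACKGROUND_SIZE, length))
        w = cls._weights(length)
        scores = w[np.arange(length), idx].sum(axis=1)
        return np.sort(scores)

    def score(self, peptide: str) -> float:
        w = self._weights(len(peptide))
        try:
            return float(sum(w[i, _AA_INDEX[aa]] for i, aa in enumerate(peptide)))
        except KeyError as exc:
            raise PredictorError(f"unknown residue {exc.args[0]!r}") from None

    def percentile_rank(self, peptide: str) -> float:
        if not 8 <= len(peptide) <= 14:
            raise PredictorError(f"unsupported peptide length {len(peptide)}")
        bg = self._background(len(peptide))
        s = self.score(peptide)
        n_better = len(bg) - int(np.searchsorted(bg, s, side="right"))
        return 100.0 * n_better / len(bg)

    def __call__(self, peptide: str) -> float:
        return self.percentile_rank(peptide)


def predict_binders(
    peptides: Iterable[str],
    predictor: Callable[[str], float] | None = None,
) -> list[BinderPrediction]:
    """Percentile ranks + strong/weak/non classes via a pluggable predictor.

    ``predictor`` maps a peptide to a percentile rank in [0, 100]; the
    built-in position-weight scorer is used when none is given.  Predictor
    failures surface as :class:`PredictorError`.
    """
    predictor = predictor or PositionWeightPredictor()
    out = []
    for pep in peptides:
        try:
            rank = float(predictor(pep))
        except PredictorError:
            raise
        except Exception as exc:  # typed error, never a silent skip
            raise PredictorError(f"predictor failed on {pep}: {exc}") from exc
        if not 0.0 <= rank <= 100.0:
            raise PredictorError(f"rank {rank} outside [0, 100] for {pep}")
        out.append(BinderPrediction(pep, rank))
    return out


def herv_fraction(
    identifications: Sequence[PeptideIdentification],
    by_sample: bool = False,
) -> float | pd.Series:
    """Fraction (percent) of hERV-ORF peptides among all identifications."""
    def _pct(idents: Sequence[PeptideIdentification]) -> float:
        if not idents:
            return 0.0
        n_herv = sum(1 for i in idents if i.category == CATEGORY_HERV_ORF)
        return 100.0 * n_herv / len(idents)

    if not by_sample:
        return _pct(identifications)
    samples = sorted({s for i in identifications for s in i.samples_detected})
    return pd.Series(
        {
            s: _pct([i for i in identifications if s in i.samples_detected])
            for s in samples
        },
        name="herv_percent",
    )


def orf_length_stats(
    identifications: Sequence[PeptideIdentification],
    search_db: Sequence[SearchDbEntry],
) -> pd.DataFrame:
    """Source ORF/CDS nucleotide-length summaries per peptide category.

    hERV peptides use the nucleotide length of their assigned source ORF
    (stop codon included); canonical peptides use the coding length
    implied by their source protein, ``3 * (n_residues + 1)``.  Returns a
    tidy frame of (category, n, median, q1, q3).
    """
    by_id = {e.entry_id: e for e in search_db}
    by_source: dict[tuple[str, str], int] = {}
    for e in search_db:
        src = str(e.provenance.get("source_id", e.entry_id))
        if e.category == CATEGORY_HERV_ORF:
            length = int(e.provenance["nt_length"])
            key = (e.category, e.entry_id)
            by_source[key] = length
        else:
            by_source[(e.category, src)] = 3 * (len(e.sequence) + 1)

    lengths: dict[str, list[int]] = {}
    for ident in identifications:
        if ident.category is None or ident.source_assigned is None:
            continue
        if ident.category == CATEGORY_HERV_ORF:
            # shortest ORF of the assigned hERV that contains the peptide
            cands = [
                int(e.provenance["nt_length"])
                for e in search_db
                if e.category == CATEGORY_HERV_ORF
                and str(e.provenance["source_id"]) == ident.source_assigned
                and ident.peptide in e.sequence
            ]
            if not cands:
                continue
            nt = min(cands)
        else:
            key = (ident.category, ident.source_assigned)
            if key not in by_source:
                continue
            nt = by_source[key]
        lengths.setdefault(ident.category, []).append(nt)

    rows = []
    for category, vals in sorted(lengths.items()):
        arr = np.array(vals, dtype=float)
        rows.append(
            {
                "category": category,
                "n": len(arr),
                "median": float(np.median(arr)),
                "q1": float(np.percentile(arr, 25)),
                "q3": float(np.percentile(arr, 75)),
            }
        )
    return pd.DataFrame(rows, columns=["category", "n", "median", "q1", "q3"])
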