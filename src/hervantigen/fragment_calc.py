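"""Monoisotopic peptide mass arithmetic and spectrum matching.

Implements the b/y fragment-ion bookkeeping used to annotate HLA-ligand
MS/MS spectra and to validate an endogenous identification against its
synthetic-peptide spectrum: neutral peptide mass, singly-to-quadruply
charged precursor and fragment m/z, tolerance-based peak matching
(fragment tolerance in Da, precursor tolerance in ppm), a label-level
spectrum similarity, and a deterministic stand-in PSM scorer.

Monoisotopic masses are used throughout (Orbitrap HCD convention);
methionine oxidation adds 15.994915 Da per site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

PROTON = 1.007276
WATER = 18.010565
OXIDATION = 15.994915

#: standard monoisotopic residue masses (Da)
RESIDUE_MASS: dict[str, float] = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047679, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}


@dataclass(frozen=True)
class IonSeries:
    """Theoretical b/y fragment ions of a peptide at one charge state."""

    peptide: str
    charge: int
    b_mz: np.ndarray
    y_mz: np.ndarray
    precursor_mz: float
    modification_deltas: tuple[float, ...]

    @property
    def labels(self) -> list[str]:
        n = len(self.peptide)
        return [f"b{i}" for i in range(1, n)] + [f"y{j}" for j in range(1, n)]

    @property
    def mz(self) -> np.ndarray:
        return np.concatenate([self.b_mz, self.y_mz])


@dataclass(frozen=True)
class Spectrum:
    """An observed peak list (m/z ascending) with precursor information."""

    peaks: tuple[tuple[float, float], ...]
    precursor_mz: float
    charge: int

    def __post_init__(self) -> None:
        mz = [p[0] for p in self.peaks]
        if any(b < a for a, b in zip(mz, mz[1:])):
            object.__setattr__(self, "peaks", tuple(sorted(self.peaks)))
        if any(p[1] < 0 for p in self.peaks):
            raise ValueError("negative peak intensity")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks], dtype=float)

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks], dtype=float)


def _residue_deltas(peptide: str, mods: Mapping[int, float] | None) -> tuple[float, ...]:
    """Per-residue modification deltas; ``mods`` maps 1-based position -> Da."""
    deltas = [0.0] * len(peptide)
    for pos, delta in (mods or {}).items():
        if not 1 <= pos <= len(peptide):
            raise ValueError(f"modification position {pos} outside peptide")
        deltas[pos - 1] += delta
    return tuple(deltas)


def peptide_mass(peptide: str, mods: Mapping[int, float] | None = None) -> float:
    """Neutral monoisotopic mass of ``peptide`` (Da), including water."""
    if not peptide:
        raise ValueError("empty peptide")
    try:
        residues = sum(RESIDUE_MASS[aa] for aa in peptide)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    return residues + sum(_residue_deltas(peptide, mods)) + WATER


def ion_series(
    peptide: str,
    charge: int = 1,
    mods: Mapping[int, float] | None = None,
) -> IonSeries:
    """Theoretical b/y ion m/z arrays (length n-1 each) plus precursor m/z."""
    if not 1 <= charge <= 4:
        raise ValueError(f"charge must be between 1+ and 4+, got {charge}")
    deltas = _residue_deltas(peptide, mods)
    masses = np.array([RESIDUE_MASS[aa] for aa in peptide]) + np.array(deltas)
    prefix = np.cumsum(masses)[:-1]                # b_1 .. b_{n-1}
    suffix = np.cumsum(masses[::-1])[:-1]          # y_1 .. y_{n-1}
    b_mz = (prefix + charge * PROTON) / charge
    y_mz = (suffix + WATER + charge * PROTON) / charge
    precursor = (masses.sum() + WATER + charge * PROTON) / charge
    return IonSeries(peptide, charge, b_mz, y_mz, precursor, deltas)


@dataclass(frozen=True)
class MatchReport:
    """Result of matching theoretical ions against an observed spectrum."""

    matched: dict[str, tuple[float, float]]  # label -> (theoretical, observed)
    n_theoretical: int
    precursor_ok: bool

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    @property
    def coverage(self) -> float:
        return self.n_matched / self.n_theoretical if self.n_theoretical else 0.0


def match_spectrum(
    observed: Spectrum,
    theoretical: IonSeries,
    frag_tol: float = 0.02,
    prec_tol_ppm: float = 10.0,
) -> MatchReport:
    """Greedy nearest-peak matching of theoretical b/y ions to observed peaks.

    Each observed peak is usable at most once; each theoretical ion takes
    the nearest unclaimed peak within ``frag_tol`` (Da).  The precursor is
    checked separately at ``prec_tol_ppm`` and only flagged, never fatal.
    """
    if frag_tol <= 0 or prec_tol_ppm <= 0:
        raise ValueError("tolerances must be positive")
    prec_ok = (
        abs(observed.precursor_mz - theoretical.precursor_mz)
        <= prec_tol_ppm * 1e-6 * theoretical.precursor_mz
    )
    obs_mz = observed.mz
    taken = np.zeros(len(obs_mz), dtype=bool)
    matched: dict[str, tuple[float, float]] = {}
    labels = theoretical.labels
    theo_mz = theoretical.mz
    # match in ascending theoretical-m/z order for a deterministic contract
    for idx in np.argsort(theo_mz, kind="stable"):
        if len(obs_mz) == 0:
            break
        diffs = np.abs(obs_mz - theo_mz[idx])
        diffs[taken] = np.inf
        j = int(np.argmin(diffs))
        if diffs[j] <= frag_tol:
            taken[j] = True
            matched[labels[idx]] = (float(theo_mz[idx]), float(obs_mz[j]))
    return MatchReport(matched, len(labels), prec_ok)


def compare_spectra(
    a: Spectrum,
    b: Spectrum,
    theoretical: IonSeries,
    frag_tol: float = 0.02,
) -> float:
    """Annotated-ion similarity of two spectra of the same peptide.

    Both spectra are annotated against ``theoretical``; the similarity is
    the Jaccard index of the two matched ion-label sets (1.0 identical
    annotation, 0.0 disjoint).  Symmetric in ``a`` and ``b``.
    """
    if not a.peaks or not b.peaks:
        raise ValueError("cannot compare an empty spectrum")
    la = set(match_spectrum(a, theoretical, frag_tol=frag_tol).matched)
    lb = set(match_spectrum(b, theoretical, frag_tol=frag_tol).matched)
    union = la | lb
    if not union:
        return 0.0
    return len(la & lb) / len(union)


def score_psm(
    observed: Spectrum,
    peptide: str,
    charge: int = 1,
    mods: Mapping[int, float] | None = None,
    frag_tol: float = 0.02,
) -> float:
    """Deterministic stand-in search-engine score.

    Sum over matched b/y ions of ``log(1 + intensity)`` of the claimed
    peak; 0 for an empty spectrum.  Monotonically nondecreasing as
    matching peaks are added.
    """
    if not observed.peaks:
        return 0.0
    series = ion_series(peptide, charge=charge, mods=mods)
    report = match_spectrum(observed, series, frag_tol=frag_tol, prec_tol_ppm=1e6)
    intens = {round(mz, 9): inten for mz, inten in observed.peaks}
    score = 0.0
    for _theo, obs in report.matched.values():
        score += math.log1p(intens.get(round(obs, 9), 0.0))
    return score


def simulate_spectrum(
    peptide: str,
    charge: int = 1,
    mods: Mapping[int, float] | None = None,
    keep_fraction: float = 1.0,
    mz_jitter: float = 0.0,
    rng: np.random.Generator | None = None,
    mz_range: tuple[float, float] | None = None,
) -> Spectrum:
    """Build a noiseless-to-jittered spectrum from a peptide's b/y ions.

    Used by the synthetic-data layer to emulate an acquired MS/MS scan:
    a random subset (``keep_fraction``) of the theoretical ions survives,
    each m/z is jittered by Normal(0, ``mz_jitter``), and peaks outside
    ``mz_range`` are discarded.
    """
    rng = rng or np.random.default_rng(0)
    series = ion_series(peptide, charge=charge, mods=mods)
    peaks: list[tuple[float, float]] = []
    for mz in series.mz:
        if keep_fraction < 1.0 and rng.random() > keep_fraction:
            continue
        obs = float(mz + rng.normal(0.0, mz_jitter)) if mz_jitter else float(mz)
        if mz_range and not (mz_range[0] <= obs <= mz_range[1]):
            continue
        peaks.append((obs, float(rng.uniform(1e3, 1e6))))
    return Spectrum(tuple(sorted(peaks)), series.precursor_mz, charge)
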