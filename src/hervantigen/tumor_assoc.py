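"""Tumor-association of hERV-derived HLA ligands.

Given per-sample validated identifications, hERV expression, binder
predictions and optionally qPCR Ct values, this module finds candidate
tumor-associated antigens: peptides detected exclusively in tumor tissue,
whose source hERV is overexpressed in the tumor (TPM fold change above a
configurable gate), and which are predicted strong HLA binders.  It also
computes ΔΔCt relative expression from qPCR and exact-sequence sharing of
hERV peptides between patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .peptidome_stats import STRONG_RANK
from .psm_pipeline import PeptideIdentification
from .search_db import CATEGORY_HERV_ORF

DEFAULT_PSEUDOCOUNT = 0.01  # TPM; guards silent hERVs in ratios
DEFAULT_MIN_FC = 2.0


@dataclass(frozen=True)
class ExpressionRecord:
    herv_id: str
    tpm_tumor: float
    tpm_normal: float
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        if self.tpm_tumor < 0 or self.tpm_normal < 0:
            raise ValueError("TPM must be >= 0")

    @property
    def fold_change(self) -> float:
        return fold_change(self.tpm_tumor, self.tpm_normal, self.pseudocount)


@dataclass(frozen=True)
class CandidateAntigen:
    peptide: str
    source_herv: str
    tumor_exclusive: bool
    expression_fc: float
    binder_rank: float
    reasons: tuple[str, ...] = ()  # empty iff all gates passed

    @property
    def passed(self) -> bool:
        return not self.reasons


@dataclass(frozen=True)
class VennPartition:
    tumor_only: frozenset[str]
    shared: frozenset[str]
    normal_only: frozenset[str]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.tumor_only), len(self.shared), len(self.normal_only))


def exclusivity_venn(
    tumor_peptides: Iterable[str], normal_peptides: Iterable[str]
) -> VennPartition:
    """Disjoint partition of peptides into tumor-only / shared / normal-only."""
    t, n = frozenset(tumor_peptides), frozenset(normal_peptides)
    return VennPartition(t - n, t & n, n - t)


def fold_change(tpm_tumor: float, tpm_normal: float, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Tumor/normal expression ratio with a pseudocount on both terms."""
    if tpm_tumor < 0 or tpm_normal < 0:
        raise ValueError("TPM must be >= 0")
    return (tpm_tumor + pseudocount) / (tpm_normal + pseudocount)


def ddct_fold_change(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.Series:
    """Relative expression per sample by the ΔΔCt method.

    ``ct`` is a tidy table with columns ``sample``, ``gene``, ``ct``
    (one row per replicate well).  Replicates are averaged (arithmetic
    mean of Ct), ΔCt = Ct(target) − Ct(reference) per sample,
    ΔΔCt = ΔCt(sample) − ΔCt(calibrator), and FC = 2^(−ΔΔCt); the
    calibrator's FC is exactly 1.
    """
    required = {"sample", "gene", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    mean_ct = ct.groupby(["sample", "gene"])["ct"].mean().unstack("gene")
    for gene in (target_gene, reference_gene):
        if gene not in mean_ct.columns or mean_ct[gene].isna().any():
            missing = (
                mean_ct.index[mean_ct[gene].isna()].tolist()
                if gene in mean_ct.columns
                else mean_ct.index.tolist()
            )
            raise ValueError(f"gene {gene!r} missing in samples {missing}")
    dct = mean_ct[target_gene] - mean_ct[reference_gene]
    if calibrator_sample not in dct.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent from Ct table")
    ddct = dct - dct.loc[calibrator_sample]
    fc = np.power(2.0, -ddct)
    fc.loc[calibrator_sample] = 1.0
    fc.name = "fold_change"
    return fc


def cross_patient_overlap(
    peptide_sets: Mapping[str, Iterable[str]],
) -> dict[tuple[str, str], frozenset[str]]:
    """Exact-sequence peptide intersection for every pair of patients.

    Sharing is by identical sequence (no L/I expansion): the question is
    whether the same reported ligand recurs across individuals.
    """
    sets = {k: frozenset(v) for k, v in peptide_sets.items()}
    if len(sets) < 2:
        raise ValueError("cross-patient overlap needs at least 2 patients")
    return {
        (a, b): sets[a] & sets[b] for a, b in combinations(sorted(sets), 2)
    }


def rank_candidates(
    identifications: Sequence[PeptideIdentification],
    venn: VennPartition,
    expression: Mapping[str, ExpressionRecord],
    binder_ranks: Mapping[str, float],
    min_fc: float = DEFAULT_MIN_FC,
    max_rank: float = STRONG_RANK,
) -> list[CandidateAntigen]:
    """Rank hERV-ORF peptides as tumor-associated antigen candidates.

    Gates: detected exclusively in tumor tissue; source-hERV tumor/normal
    fold change >= ``min_fc``; predicted binder percentile rank <
    ``max_rank``.  Passing candidates come first, ordered by (fold change
    descending, rank ascending); failing peptides follow, each carrying
    its failure reasons (``not_tumor_exclusive``, ``low_fc``,
    ``weak_binder``).  ``min_fc=1`` disables the expression gate.
    """
    out: list[CandidateAntigen] = []
    for ident in identifications:
        if ident.category != CATEGORY_HERV_ORF:
            continue
        herv = ident.source_assigned or ""
        expr = expression.get(herv)
        fc = expr.fold_change if expr is not None else 0.0
        rank = binder_ranks.get(ident.peptide, 100.0)
        reasons = []
        if ident.peptide not in venn.tumor_only:
            reasons.append("not_tumor_exclusive")
        if fc < min_fc:
            reasons.append("low_fc")
        if rank >= max_rank:
            reasons.append("weak_binder")
        out.append(
            CandidateAntigen(
                peptide=ident.peptide,
                source_herv=herv,
                tumor_exclusive=ident.peptide in venn.tumor_only,
                expression_fc=fc,
                binder_rank=rank,
                reasons=tuple(reasons),
            )
        )
    out.sort(key=lambda c: (not c.passed, -c.expression_fc, c.binder_rank, c.peptide))
    return out
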