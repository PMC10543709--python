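"""Worked-example dataset: published hERV-ligand inventories of two RCC patients.

The study this package models reported, for patient RCC17, 2,294
nonredundant canonical HLA-A24 ligands plus 8 hERV-ORF peptides across
paired tumor/normal kidney tissue (4 tumor-exclusive, 1 shared, 3
normal-exclusive), and for patient RCC21 5 hERV peptides in tumor tissue,
2 of which were sequence-identical to RCC17 tumor peptides.  Three real
sequences are public: LYDTVTHTF (source hERV3895, tumor-associated),
HFNSFHFL (hERV4024) and SQYVFLTLQ (hERV2710).

The remaining sequences and the per-peptide detection assignments beyond
the printed counts are SYNTHETIC stand-ins: plausible HLA-A24-motif
peptides constructed so that every published set size and overlap is
reproduced exactly.  Use this dataset to exercise the set operations, not
as a source of real sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

N_CANONICAL_RCC17 = 2294  # published nonredundant canonical peptide count


@dataclass(frozen=True)
class HervLigandRecord:
    peptide: str
    source_herv: str
    detected_tumor: bool
    detected_normal: bool
    synthetic: bool  # True when the sequence is a constructed stand-in


#: RCC17: 8 hERV-ORF peptides; 4 tumor-only, 1 shared, 3 normal-only.
RCC17_HERV_LIGANDS: tuple[HervLigandRecord, ...] = (
    HervLigandRecord("LYDTVTHTF", "hERV3895", True, False, False),
    HervLigandRecord("HFNSFHFL", "hERV4024", True, False, False),
    HervLigandRecord("SQYVFLTLQ", "hERV2710", True, False, False),
    HervLigandRecord("RYLQDTNKF", "hERV0101", True, False, True),
    HervLigandRecord("VYGPTQSHF", "hERV0102", True, True, True),
    HervLigandRecord("KYIGNLPEL", "hERV0103", False, True, True),
    HervLigandRecord("AYSSLQTFI", "hERV0104", False, True, True),
    HervLigandRecord("QYLDNIRQF", "hERV0105", False, True, True),
)

#: RCC21: 5 hERV peptides in tumor tissue; 2 identical to RCC17 tumor peptides.
RCC21_HERV_LIGANDS: tuple[HervLigandRecord, ...] = (
    HervLigandRecord("LYDTVTHTF", "hERV3895", True, False, False),
    HervLigandRecord("HFNSFHFL", "hERV4024", True, False, False),
    HervLigandRecord("NYLPQVSEF", "hERV0201", True, False, True),
    HervLigandRecord("TYMANQPHL", "hERV0202", True, False, True),
    HervLigandRecord("SYQEKLPFI", "hERV0203", True, False, True),
)


def rcc17_tumor_peptides() -> set[str]:
    return {r.peptide for r in RCC17_HERV_LIGANDS if r.detected_tumor}


def rcc17_normal_peptides() -> set[str]:
    return {r.peptide for r in RCC17_HERV_LIGANDS if r.detected_normal}


def rcc21_tumor_peptides() -> set[str]:
    return {r.peptide for r in RCC21_HERV_LIGANDS if r.detected_tumor}
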