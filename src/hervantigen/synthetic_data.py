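"""Seeded generators for every input the pipeline consumes.

The generators emulate a paired tumor/normal HLA class I immunopeptidome
experiment at desk scale: a random canonical proteome with per-sample
expression, a panel of hERV transcripts — exactly one of which carries a
planted HLA-A24-motif antigen encoded at the 3' end of a short cryptic
ORF and is overexpressed in the tumor (default 7.7-fold) — somatic
missense/frameshift mutations with back-translated CDS, concatenated
target-decoy PSM score lists with known true/false labels, and a
triplicate qPCR Ct table consistent with the planted fold change.

Everything is deterministic per seed; each generator draws from its own
seed stream so outputs do not depend on call order.  The planted antigen
is guaranteed novel: if it (or any Leu/Ile-isobaric variant) collides
with the random canonical proteome, the offending protein is redrawn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .psm_pipeline import PsmRecord, expand_leu_ile
from .search_db import (
    AA_ALPHABET,
    CATEGORY_HERV_ORF,
    HervTranscript,
    ProteinRecord,
    SearchDbEntry,
    SomaticMutation,
)

TUMOR = "tumor"
NORMAL = "normal"

#: codons per amino acid (standard genetic code), for back-translation
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_BY_AA:
    _CODONS_BY_AA[aa].sort()

_NON_STOP_CODONS = sorted(standard_dna_table.forward_table)
_NT = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated experiment.

    Defaults reflect the scale and effect sizes of a single-patient
    tumor/normal immunopeptidome study: ~2,300 identified peptides with
    9-mer dominance and HLA-A24 anchor bias, 322 missense and 14
    frameshift somatic mutations, 8 true hERV-ORF peptides, a planted
    tumor-only 9-mer antigen whose source hERV is overexpressed 7.7-fold
    in the tumor, and an acquisition window of m/z 350-2,000 with charge
    states 1+ to 4+.
    """

    seed: int = 0
    n_proteins: int = 250
    protein_len_range: tuple[int, int] = (100, 400)
    n_hervs: int = 40
    herv_len_range: tuple[int, int] = (600, 2000)
    n_missense: int = 322
    n_frameshift: int = 14
    planted_antigen: str = "LYDTVTHTF"
    planted_herv_id: str = "hERV3895"
    planted_herv_fc: float = 7.7
    n_target_psms: int = 2300
    n_true_peptides: int = 1300
    n_herv_true_peptides: int = 8
    planted_psm_count: int = 3
    n_false_target_psms: int = 1000
    n_decoy_psms: int = 1000
    target_score_mean: float = 4.5
    decoy_score_mean: float = 0.0
    score_sd: float = 1.0
    decoy_mode: str = "reversed"  # "reversed" | "random"
    acquisition_window: tuple[float, float] = (350.0, 2000.0)
    charge_range: tuple[int, int] = (1, 4)
    reference_gene: str = "G3PDH"

    def __post_init__(self) -> None:
        if not 8 <= len(self.planted_antigen) <= 12:
            raise ValueError("planted antigen must be an 8-12 mer")
        if set(self.planted_antigen) - set(AA_ALPHABET):
            raise ValueError("planted antigen has non-standard residues")
        if self.planted_herv_fc <= 1:
            raise ValueError("planted hERV fold change must exceed 1")
        for name in (
            "n_proteins", "n_hervs", "n_missense", "n_frameshift",
            "n_target_psms", "n_decoy_psms", "n_false_target_psms",
            "n_true_peptides", "n_herv_true_peptides", "planted_psm_count",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for lo, hi in (self.protein_len_range, self.herv_len_range):
            if lo < 1 or hi < lo:
                raise ValueError("invalid length range")
        if self.decoy_score_mean >= self.target_score_mean:
            raise ValueError("decoy score mean must be below target score mean")
        if not 1 <= self.charge_range[0] <= self.charge_range[1] <= 4:
            raise ValueError("charge range must lie within 1..4")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent deterministic stream per generator
    return np.random.default_rng([config.seed, 7919, stream])


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def _forbidden_fragments(config: SimConfig) -> set[str]:
    # the antigen and every isobaric variant must stay out of the canonical space
    return expand_leu_ile(config.planted_antigen, "combinatorial")


def _contains_forbidden(seq: str, forbidden: set[str]) -> bool:
    return any(f in seq for f in forbidden)


def generate_proteome(config: SimConfig) -> list[ProteinRecord]:
    """Random canonical proteome with tumor/normal TPM > 0 for every protein."""
    rng = _rng(config, 1)
    lo, hi = config.protein_len_range
    forbidden = _forbidden_fragments(config)
    records: list[ProteinRecord] = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_peptide(rng, length)
        while _contains_forbidden(seq, forbidden):  # preserve ground-truth novelty
            seq = _random_peptide(rng, length)
        tpm = {
            TUMOR: float(rng.lognormal(mean=2.0, sigma=1.0)),
            NORMAL: float(rng.lognormal(mean=2.0, sigma=1.0)),
        }
        records.append(
            ProteinRecord(
                id=f"PROT{i + 1:04d}",
                gene_id=f"GENE{i + 1:04d}",
                sequence=seq,
                tpm=tpm,
            )
        )
    return records


def back_translate(
    peptide: str, rng: np.random.Generator
) -> str:
    """Back-translate a peptide choosing uniformly among synonymous codons."""
    return "".join(
        _CODONS_BY_AA[aa][int(rng.integers(len(_CODONS_BY_AA[aa])))] for aa in peptide
    )


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_NT), size=length))


def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=n_codons)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


def generate_hervs(config: SimConfig) -> list[HervTranscript]:
    """hERV transcript panel with the planted antigen-bearing transcript.

    Exactly one transcript (``config.planted_herv_id``) encodes the
    planted antigen as the suffix of a short cryptic ORF that is not the
    transcript's first ORF; its tumor TPM equals ``planted_herv_fc``
    times its normal TPM.  The other transcripts are random sequence with
    one embedded random ORF each; a minority are silent (TPM 0) in one
    sample to exercise the expression filter.
    """
    rng = _rng(config, 2)
    lo, hi = config.herv_len_range
    transcripts: list[HervTranscript] = []

    planted_index = int(rng.integers(config.n_hervs)) if config.n_hervs > 0 else 0
    for i in range(config.n_hervs):
        if i == planted_index:
            # upstream decoy ORF so the cryptic ORF is not the first one
            prefix = _random_nt(rng, int(rng.integers(90, 240)))
            decoy_orf = "ATG" + _random_coding(rng, int(rng.integers(20, 40))) + "TAA"
            spacer = _random_nt(rng, int(rng.integers(30, 90)))
            filler = _random_coding(rng, int(rng.integers(8, 20)))
            antigen_nt = back_translate(config.planted_antigen, rng)
            # in-frame TAA immediately upstream pins the ORF start at this ATG
            cryptic = "TAA" + "ATG" + filler + antigen_nt + "TGA"
            tail = _random_nt(rng, int(rng.integers(50, 150)))
            seq = prefix + decoy_orf + spacer + cryptic + tail
            normal_tpm = 1.0
            tpm = {TUMOR: config.planted_herv_fc * normal_tpm, NORMAL: normal_tpm}
            transcripts.append(HervTranscript(config.planted_herv_id, seq, tpm))
            continue
        length = int(rng.integers(lo, hi + 1))
        n_codons = int(rng.integers(12, 61))
        orf = "ATG" + _random_coding(rng, n_codons) + "TAA"
        body = _random_nt(rng, max(length - len(orf), 10))
        insert_at = int(rng.integers(0, len(body) + 1))
        seq = body[:insert_at] + orf + body[insert_at:]
        normal_tpm = float(rng.lognormal(mean=0.7, sigma=1.0))
        ratio = float(rng.lognormal(mean=0.0, sigma=0.5))
        tpm = {TUMOR: normal_tpm * ratio, NORMAL: normal_tpm}
        if rng.random() < 0.15:  # occasionally silent in one sample
            tpm[TUMOR if rng.random() < 0.5 else NORMAL] = 0.0
        transcripts.append(HervTranscript(f"hERV{i + 1:04d}", seq, tpm))
    return transcripts


def generate_mutations(
    config: SimConfig, proteome: Sequence[ProteinRecord]
) -> tuple[list[SomaticMutation], dict[str, str]]:
    """Somatic missense substitutions and 1-nt frameshift indels.

    Returns the mutation list and a CDS per mutated gene (random
    synonymous back-translation plus stop codon) so frameshift
    translations are computable downstream.
    """
    if not proteome and (config.n_missense or config.n_frameshift):
        raise ValueError("cannot place mutations on an empty proteome")
    rng = _rng(config, 3)
    n_positions = sum(len(p.sequence) for p in proteome)
    if config.n_missense + config.n_frameshift > n_positions:
        raise ValueError("more mutations requested than available positions")

    mutations: list[SomaticMutation] = []
    cds_by_gene: dict[str, str] = {}
    used: set[tuple[str, int]] = set()
    aa_list = list(AA_ALPHABET)

    for _ in range(config.n_missense):
        while True:
            prot = proteome[int(rng.integers(len(proteome)))]
            pos = int(rng.integers(1, len(prot.sequence) + 1))
            if (prot.gene_id, pos) not in used:
                used.add((prot.gene_id, pos))
                break
        ref = prot.sequence[pos - 1]
        alt = ref
        while alt == ref:
            alt = aa_list[int(rng.integers(len(aa_list)))]
        mutations.append(
            SomaticMutation(
                gene_id=prot.gene_id, type="missense",
                protein_position=pos, ref_aa=ref, alt_aa=alt,
            )
        )

    for _ in range(config.n_frameshift):
        prot = proteome[int(rng.integers(len(proteome)))]
        if prot.gene_id not in cds_by_gene:
            cds_by_gene[prot.gene_id] = back_translate(prot.sequence, rng) + "TAA"
        cds = cds_by_gene[prot.gene_id]
        pos = int(rng.integers(1, len(cds) - 3))
        if rng.random() < 0.5:
            mutations.append(
                SomaticMutation(
                    gene_id=prot.gene_id, type="frameshift",
                    cds_position=pos, inserted=_NT[int(rng.integers(4))],
                )
            )
        else:
            mutations.append(
                SomaticMutation(
                    gene_id=prot.gene_id, type="frameshift",
                    cds_position=pos, deleted=1,
                )
            )
    return mutations, cds_by_gene


@dataclass(frozen=True)
class SimulatedPsms:
    """PSM table plus the ground truth needed for parameter-recovery tests."""

    psms: list[PsmRecord]
    is_true: list[bool]  # aligned with psms; decoys are False
    true_peptides: frozenset[str]
    herv_true_peptides: frozenset[str]


def _sample_window(
    rng: np.random.Generator,
    entries: Sequence[SearchDbEntry],
    lengths: Sequence[int],
    length_p: Sequence[float],
    want_y2: bool,
    want_cterm: bool,
    max_tries: int = 400,
) -> str:
    """Rejection-sample a substring of the database with optional anchor motif."""
    weights = np.array([len(e.sequence) for e in entries], dtype=float)
    weights /= weights.sum()
    for attempt in range(max_tries):
        length = int(rng.choice(lengths, p=length_p))
        e = entries[int(rng.choice(len(entries), p=weights))]
        if len(e.sequence) < length:
            continue
        start = int(rng.integers(0, len(e.sequence) - length + 1))
        pep = e.sequence[start : start + length]
        if want_y2 and pep[1] != "Y":
            continue
        if want_cterm and pep[-1] not in "FLI":
            continue
        return pep
    # motif not found in the available sequence space: accept any window
    length = int(rng.choice(lengths, p=length_p))
    e = entries[int(np.argmax(weights))]
    start = int(rng.integers(0, max(len(e.sequence) - length, 0) + 1))
    return e.sequence[start : start + length]


LENGTHS = (8, 9, 10, 11, 12)
LENGTH_P = (0.10, 0.60, 0.15, 0.10, 0.05)  # 9-mer dominance
P_ANCHOR_Y2 = 0.70
P_ANCHOR_CTERM = 0.80


def generate_psms(
    config: SimConfig,
    search_db: Sequence[SearchDbEntry] | Mapping[str, Sequence[SearchDbEntry]],
) -> SimulatedPsms:
    """Concatenated target-decoy PSM lists with known labels.

    True-target PSMs are windows of database sequences (9-mer-dominated
    lengths, HLA-A24-like anchor bias) scored Normal(target_score_mean,
    score_sd); the planted antigen appears only in the tumor sample.
    False-target PSMs are unbiased database windows and decoy PSMs are
    reversed (or random) peptides, both scored Normal(decoy_score_mean,
    score_sd).  False targets and decoys are generated in matched numbers
    by default so the decoy count estimates the false-target count.
    """
    if isinstance(search_db, Mapping):
        db_by_sample = {s: list(v) for s, v in search_db.items()}
    else:
        db_by_sample = {TUMOR: list(search_db), NORMAL: list(search_db)}
    if not any(db_by_sample.values()):
        raise ValueError("empty search database")
    rng = _rng(config, 4)
    samples = sorted(db_by_sample)

    # entries indexable in every sample they may be detected in
    common_ids = set.intersection(*(set(e.entry_id for e in v) for v in db_by_sample.values()))
    any_db = next(iter(db_by_sample.values()))
    common = [e for e in any_db if e.entry_id in common_ids]
    common_herv = [e for e in common if e.category == CATEGORY_HERV_ORF]
    common_other = [e for e in common if e.category != CATEGORY_HERV_ORF]

    def draw_pattern() -> tuple[str, ...]:
        r = rng.random()
        if len(samples) < 2:
            return tuple(samples)
        if r < 0.3:
            return (TUMOR,)
        if r < 0.6:
            return (NORMAL,)
        return tuple(samples)

    forbidden = _forbidden_fragments(config)
    true_pool: list[tuple[str, tuple[str, ...]]] = []
    n_plain = max(config.n_true_peptides - config.n_herv_true_peptides, 0)
    source = common_other or common
    for _ in range(n_plain):
        pep = _sample_window(
            rng, source, LENGTHS, LENGTH_P,
            rng.random() < P_ANCHOR_Y2, rng.random() < P_ANCHOR_CTERM,
        )
        true_pool.append((pep, draw_pattern()))
    herv_peps: set[str] = set()
    if common_herv:
        for _ in range(config.n_herv_true_peptides):
            pep = _sample_window(
                rng, common_herv, LENGTHS, LENGTH_P,
                rng.random() < P_ANCHOR_Y2, rng.random() < P_ANCHOR_CTERM,
            )
            if pep in forbidden:
                continue  # the planted antigen is added explicitly, tumor-only
            herv_peps.add(pep)
            true_pool.append((pep, draw_pattern()))

    psms: list[PsmRecord] = []
    labels: list[bool] = []
    charges = list(range(config.charge_range[0], config.charge_range[1] + 1))
    charge_p = np.ones(len(charges)) / len(charges)
    if len(charges) == 4:
        charge_p = np.array([0.15, 0.50, 0.25, 0.10])

    def emit(peptide: str, mean: float, sample: str, true: bool) -> None:
        mods = ""
        if "M" in peptide and rng.random() < 0.2:
            mods = f"Oxidation@{peptide.index('M') + 1}"
        psms.append(
            PsmRecord(
                peptide=peptide,
                score=float(rng.normal(mean, config.score_sd)),
                is_decoy=False,
                sample=sample,
                charge=int(rng.choice(charges, p=charge_p)),
                modifications=mods,
            )
        )
        labels.append(true)

    # true-target PSMs
    if true_pool:
        for _ in range(config.n_target_psms):
            pep, pattern = true_pool[int(rng.integers(len(true_pool)))]
            sample = pattern[int(rng.integers(len(pattern)))]
            emit(pep, config.target_score_mean, sample, True)
    # the planted antigen: tumor-only true PSMs
    if TUMOR in db_by_sample:
        for _ in range(config.planted_psm_count):
            emit(config.planted_antigen, config.target_score_mean, TUMOR, True)

    # false-target PSMs: unbiased db windows at decoy-like scores
    for _ in range(config.n_false_target_psms):
        pep = _sample_window(rng, common or any_db, LENGTHS, LENGTH_P, False, False)
        sample = samples[int(rng.integers(len(samples)))]
        emit(pep, config.decoy_score_mean, sample, False)

    # decoys: reversals of fresh unbiased db windows, so decoy peptides have
    # the same multiplicity profile as the false-target matches they estimate
    for _ in range(config.n_decoy_psms):
        if config.decoy_mode == "reversed":
            pep = _sample_window(rng, common or any_db, LENGTHS, LENGTH_P, False, False)[::-1]
        else:
            length = int(rng.choice(LENGTHS, p=LENGTH_P))
            pep = _random_peptide(rng, length)
        sample = samples[int(rng.integers(len(samples)))]
        psms.append(
            PsmRecord(
                peptide=pep,
                score=float(rng.normal(config.decoy_score_mean, config.score_sd)),
                is_decoy=True,
                sample=sample,
                charge=int(rng.choice(charges, p=charge_p)),
            )
        )
        labels.append(False)

    true_set = frozenset(p for p, _ in true_pool) | (
        {config.planted_antigen} if TUMOR in db_by_sample else frozenset()
    )
    return SimulatedPsms(psms, labels, true_set, frozenset(herv_peps | {config.planted_antigen}))


def generate_ct_table(
    config: SimConfig,
    samples: Sequence[str] = (TUMOR, NORMAL),
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Triplicate qPCR Ct values for the planted hERV and the reference gene.

    The planted hERV's Ct is lower in tumor by log2(planted_herv_fc)
    cycles relative to normal, after normalization to the reference gene,
    so the ΔΔCt method recovers the planted fold change.
    """
    rng = _rng(config, 5)
    rows = []
    base_dct = 8.0  # low basal hERV expression relative to the housekeeping gene
    for sample in samples:
        ref_level = float(rng.normal(20.0, 0.3))
        dct = base_dct - (np.log2(config.planted_herv_fc) if sample == TUMOR else 0.0)
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample": sample,
                    "gene": config.reference_gene,
                    "replicate": rep,
                    "ct": ref_level + float(rng.normal(0.0, 0.05)),
                }
            )
            rows.append(
                {
                    "sample": sample,
                    "gene": config.planted_herv_id,
                    "replicate": rep,
                    "ct": ref_level + dct + float(rng.normal(0.0, 0.05)),
                }
            )
    return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])


# ---------------------------------------------------------------------------
# file emission


def write_dataset(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every input file the pipeline consumes, plus ground truth.

    Writes canonical proteome FASTA, hERV FASTA, expression TSV, mutation
    TSV, PSM TSV, Ct TSV and a ground-truth JSON (planted antigen and
    hERV, true/false PSM labels).  Returns the paths keyed by role.
    """
    from . import io as hio  # local import to avoid a cycle
    from .search_db import assemble_database

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteome = generate_proteome(config)
    hervs = generate_hervs(config)
    mutations, cds_by_gene = generate_mutations(config, proteome)
    dbs = {
        s: assemble_database(proteome, mutations, hervs, sample=s, cds_by_gene=cds_by_gene)
        for s in (TUMOR, NORMAL)
    }
    sim = generate_psms(config, dbs)
    ct = generate_ct_table(config)

    paths = {
        "canonical_fasta": outdir / "canonical.fasta",
        "herv_fasta": outdir / "hervs.fasta",
        "expression_tsv": outdir / "expression.tsv",
        "mutations_tsv": outdir / "mutations.tsv",
        "cds_fasta": outdir / "mutated_cds.fasta",
        "psms_tsv": outdir / "psms.tsv",
        "ct_tsv": outdir / "ct.tsv",
        "truth_json": outdir / "ground_truth.json",
    }
    hio.write_protein_fasta(paths["canonical_fasta"], proteome)
    hio.write_herv_fasta(paths["herv_fasta"], hervs)
    hio.write_expression_tsv(paths["expression_tsv"], proteome, hervs)
    hio.write_mutations_tsv(paths["mutations_tsv"], mutations)
    hio.write_plain_fasta(paths["cds_fasta"], cds_by_gene)
    hio.write_psms_tsv(paths["psms_tsv"], sim.psms)
    ct.to_csv(paths["ct_tsv"], sep="\t", index=False)
    truth = {
        "planted_antigen": config.planted_antigen,
        "planted_herv_id": config.planted_herv_id,
        "planted_herv_fc": config.planted_herv_fc,
        "true_peptides": sorted(sim.true_peptides),
        "herv_true_peptides": sorted(sim.herv_true_peptides),
        "psm_is_true": sim.is_true,
    }
    paths["truth_json"].write_text(json.dumps(truth, indent=1))
    return paths
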