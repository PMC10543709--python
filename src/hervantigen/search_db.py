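"""Personalized MS search-database construction.

The search space used for immunopeptidome identification is the union of
three sequence sets:

1. *canonical* — translations of expressed protein-coding transcripts;
2. *mutanome* — windows around somatic mutations (61-residue missense
   windows; frameshift windows running to the first novel stop codon);
3. *herv_orf* — three-frame translations of every ATG→stop open reading
   frame found in expressed endogenous-retrovirus (hERV) transcripts.

Only sequences whose source transcript is expressed (TPM above a
configurable threshold, default ``> 0``) in the analyzed sample enter the
database, so tumor and normal databases for the same patient may differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

CATEGORY_CANONICAL = "canonical"
CATEGORY_MUTANOME = "mutanome"
CATEGORY_HERV_ORF = "herv_orf"
CATEGORIES = (CATEGORY_CANONICAL, CATEGORY_MUTANOME, CATEGORY_HERV_ORF)

#: residues flanking a missense site retained in a mutanome entry
MUTANOME_FLANK = 30


@dataclass(frozen=True)
class ProteinRecord:
    """A canonical protein with per-sample transcript expression (TPM)."""

    id: str
    gene_id: str
    sequence: str
    tpm: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(AA_ALPHABET)
        if bad:
            raise ValueError(f"non-standard residues in {self.id}: {sorted(bad)}")
        if any(v < 0 for v in self.tpm.values()):
            raise ValueError("TPM must be >= 0")


@dataclass(frozen=True)
class HervTranscript:
    """An endogenous-retrovirus transcript (nucleotide sequence + TPM)."""

    herv_id: str
    sequence: str
    tpm: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(NT_ALPHABET)
        if bad:
            raise ValueError(f"non-ACGT characters in {self.herv_id}: {sorted(bad)}")
        if any(v < 0 for v in self.tpm.values()):
            raise ValueError("TPM must be >= 0")


@dataclass(frozen=True)
class SomaticMutation:
    """A somatic mutation: missense substitution or single-nt frameshift.

    ``protein_position`` is 1-based for missense; ``cds_position`` is the
    1-based nucleotide index of the insertion point / deleted base for
    frameshifts.  ``inserted`` holds the inserted bases (insertions) and
    ``deleted`` the number of deleted bases (deletions).
    """

    gene_id: str
    type: str  # "missense" | "frameshift"
    protein_position: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    cds_position: int | None = None
    inserted: str = ""
    deleted: int = 0

    def __post_init__(self) -> None:
        if self.type == "missense":
            if self.ref_aa == self.alt_aa:
                raise ValueError("missense requires ref_aa != alt_aa")
            if self.protein_position is None or self.protein_position < 1:
                raise ValueError("missense requires a 1-based protein_position")
        elif self.type == "frameshift":
            if self.cds_position is None or self.cds_position < 1:
                raise ValueError("frameshift requires a 1-based cds_position")
            shift = (len(self.inserted) - self.deleted) % 3
            if shift == 0:
                raise ValueError("frameshift indel length must not be a multiple of 3")
        else:
            raise ValueError(f"unknown mutation type {self.type!r}")


@dataclass(frozen=True)
class Orf:
    """An ATG→stop open reading frame on the forward strand of a transcript.

    Coordinates are 0-based half-open on the transcript; ``end_nt`` is the
    end of the stop codon, so ``nt_length`` includes the stop.
    """

    herv_id: str
    frame: int
    start_nt: int
    end_nt: int
    peptide: str

    def __post_init__(self) -> None:
        if (self.end_nt - self.start_nt) % 3 != 0:
            raise ValueError("ORF span must be a multiple of 3")
        if not self.peptide or self.peptide[0] != "M":
            raise ValueError("ORF peptide must start with Met")
        if "*" in self.peptide:
            raise ValueError("ORF peptide must not contain internal stops")

    @property
    def nt_length(self) -> int:
        return self.end_nt - self.start_nt


@dataclass(frozen=True)
class SearchDbEntry:
    """One FASTA entry of the custom search database."""

    entry_id: str
    category: str
    sequence: str
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.sequence:
            raise ValueError("empty search-db sequence")


def translate(cds: str, frame: int = 0) -> str:
    """Translate ``cds`` in the given frame with the standard genetic code.

    Translation stops at the first stop codon; a trailing partial codon is
    ignored.  Raises ``ValueError`` on non-ACGT characters or invalid frame.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    bad = set(cds) - set(NT_ALPHABET)
    if bad:
        raise ValueError(f"non-ACGT characters: {sorted(bad)}")
    sub = cds[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate(to_stop=True))


def find_orfs(
    transcript: HervTranscript | str,
    min_peptide_len: int = 8,
    all_starts: bool = False,
) -> list[Orf]:
    """Scan the forward strand in 3 frames for ATG→stop open reading frames.

    By default one ORF per (frame, stop codon) is reported, anchored at the
    5'-most ATG since the previous in-frame stop; with ``all_starts`` every
    nested ATG→stop pair is emitted.  ORFs whose transcript runs out before
    an in-frame stop are excluded, as are ORFs translating to fewer than
    ``min_peptide_len`` residues.
    """
    if isinstance(transcript, HervTranscript):
        seq = transcript.sequence
        herv_id = transcript.herv_id
    else:
        seq = transcript
        herv_id = "<anonymous>"
        bad = set(seq) - set(NT_ALPHABET)
        if bad:
            raise ValueError(f"non-ACGT characters: {sorted(bad)}")

    orfs: list[Orf] = []
    for frame in range(3):
        starts: list[int] = []
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                emit = starts if all_starts else starts[:1]
                for start in emit:
                    peptide = translate(seq[start : pos + 3])
                    if len(peptide) >= min_peptide_len:
                        orfs.append(
                            Orf(
                                herv_id=herv_id,
                                frame=frame,
                                start_nt=start,
                                end_nt=pos + 3,
                                peptide=peptide,
                            )
                        )
                starts = []
            elif codon == "ATG":
                starts.append(pos)
        # ATGs with no downstream in-frame stop are dropped by design
    orfs.sort(key=lambda o: (o.frame, o.start_nt, o.end_nt))
    return orfs


def _apply_frameshift(cds: str, mutation: SomaticMutation) -> str:
    pos = mutation.cds_position
    if pos is None or pos > len(cds):
        raise ValueError("cds_position outside CDS")
    i = pos - 1
    if mutation.deleted:
        if i + mutation.deleted > len(cds):
            raise ValueError("deletion runs past end of CDS")
        return cds[:i] + cds[i + mutation.deleted :]
    return cds[:i] + mutation.inserted + cds[i:]


def build_mutanome_entry(
    protein: ProteinRecord,
    mutation: SomaticMutation,
    cds: str | None = None,
) -> SearchDbEntry:
    """Build the mutation-centered database entry.

    Missense: the window from 30 residues upstream to 30 residues
    downstream of the mutated site (clipped at the protein ends) with the
    alternate residue substituted.  Frameshift: 30 residues upstream of the
    first altered codon followed by the shifted-frame translation up to the
    first novel stop codon (``cds`` is required).
    """
    if mutation.gene_id != protein.gene_id:
        raise ValueError("mutation/protein gene_id mismatch")

    if mutation.type == "missense":
        pos = mutation.protein_position
        assert pos is not None
        if pos > len(protein.sequence):
            raise ValueError("mutation position outside protein")
        if protein.sequence[pos - 1] != mutation.ref_aa:
            raise ValueError(
                f"reference residue mismatch at {protein.id}:{pos}: "
                f"protein has {protein.sequence[pos - 1]}, mutation says {mutation.ref_aa}"
            )
        lo = max(0, pos - 1 - MUTANOME_FLANK)
        hi = min(len(protein.sequence), pos + MUTANOME_FLANK)
        window = (
            protein.sequence[lo : pos - 1]
            + str(mutation.alt_aa)
            + protein.sequence[pos:hi]
        )
        entry_id = (
            f"mutanome|{protein.gene_id}|"
            f"{mutation.ref_aa}{pos}{mutation.alt_aa}"
        )
        provenance = {
            "source_id": protein.id,
            "gene_id": protein.gene_id,
            "mutation": f"{mutation.ref_aa}{pos}{mutation.alt_aa}",
            "site_offset": pos - 1 - lo,  # 0-based index of mutant residue in window
        }
        return SearchDbEntry(entry_id, CATEGORY_MUTANOME, window, provenance)

    # frameshift
    if cds is None:
        raise ValueError("frameshift mutanome entries require the CDS")
    mutated = _apply_frameshift(cds, mutation)
    aa_idx = (mutation.cds_position - 1) // 3  # 0-based first altered codon
    shifted = translate(mutated, 0)
    lo = max(0, aa_idx - MUTANOME_FLANK)
    window = shifted[lo:]
    if not window:
        raise ValueError("frameshift window is empty (stop at mutation site)")
    kind = f"ins{mutation.inserted}" if mutation.inserted else f"del{mutation.deleted}"
    entry_id = f"mutanome|{protein.gene_id}|fs_c{mutation.cds_position}_{kind}"
    provenance = {
        "source_id": protein.id,
        "gene_id": protein.gene_id,
        "mutation": f"fs:c.{mutation.cds_position}:{kind}",
        "site_offset": aa_idx - lo,
    }
    return SearchDbEntry(entry_id, CATEGORY_MUTANOME, window, provenance)


def assemble_database(
    canonical: Sequence[ProteinRecord],
    mutations: Iterable[SomaticMutation],
    hervs: Sequence[HervTranscript],
    sample: str,
    tpm_threshold: float = 0.0,
    cds_by_gene: Mapping[str, str] | None = None,
    min_orf_aa: int = 8,
    all_starts: bool = False,
) -> list[SearchDbEntry]:
    """Assemble the 3-part search database for one sample.

    Any source (protein transcript or hERV) with TPM <= ``tpm_threshold``
    in ``sample`` is excluded.  The result is deterministically ordered by
    (category, entry_id); duplicate entry ids raise.
    """
    cds_by_gene = cds_by_gene or {}
    by_gene = {p.gene_id: p for p in canonical}
    entries: list[SearchDbEntry] = []

    for prot in canonical:
        if prot.tpm.get(sample, 0.0) <= tpm_threshold:
            continue
        entries.append(
            SearchDbEntry(
                f"canonical|{prot.id}",
                CATEGORY_CANONICAL,
                prot.sequence,
                {"source_id": prot.id, "gene_id": prot.gene_id},
            )
        )

    for mut in mutations:
        prot = by_gene.get(mut.gene_id)
        if prot is None:
            raise ValueError(f"mutation references unknown gene {mut.gene_id}")
        if prot.tpm.get(sample, 0.0) <= tpm_threshold:
            continue
        entries.append(build_mutanome_entry(prot, mut, cds_by_gene.get(mut.gene_id)))

    for herv in hervs:
        if herv.tpm.get(sample, 0.0) <= tpm_threshold:
            continue
        for orf in find_orfs(herv, min_peptide_len=min_orf_aa, all_starts=all_starts):
            entries.append(
                SearchDbEntry(
                    f"herv_orf|{herv.herv_id}|f{orf.frame}:{orf.start_nt}-{orf.end_nt}",
                    CATEGORY_HERV_ORF,
                    orf.peptide,
                    {
                        "source_id": herv.herv_id,
                        "frame": orf.frame,
                        "start_nt": orf.start_nt,
                        "end_nt": orf.end_nt,
                        "nt_length": orf.nt_length,
                    },
                )
            )

    entries.sort(key=lambda e: (CATEGORIES.index(e.category), e.entry_id))
    seen: set[str] = set()
    for e in entries:
        if e.entry_id in seen:
            raise ValueError(f"duplicate search-db entry id {e.entry_id}")
        seen.add(e.entry_id)
    return entries
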