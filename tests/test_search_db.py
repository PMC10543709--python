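"""Search-database construction: translation, ORF finding, mutanome windows."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hervantigen.search_db import (
    CATEGORY_HERV_ORF,
    HervTranscript,
    ProteinRecord,
    SomaticMutation,
    assemble_database,
    build_mutanome_entry,
    find_orfs,
    translate,
)

# independent codon table for the brute-force ORF oracle
_GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G", "TAA": "*", "TAG": "*", "TGA": "*",
}


def brute_force_orfs(seq: str, min_peptide_len: int):
    """Exhaustive ATG x in-frame-stop scan, 5'-most ATG per (frame, stop)."""
    found = {}
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        pos = start
        peptide = []
        while pos + 3 <= len(seq):
            aa = _GENETIC_CODE[seq[pos : pos + 3]]
            if aa == "*":
                key = (start % 3, pos + 3)  # (frame, stop end)
                if key not in found or start < found[key][0]:
                    found[key] = (start, "".join(peptide))
                break
            peptide.append(aa)
            pos += 3
    return {
        (frame, start, end, pep)
        for (frame, end), (start, pep) in found.items()
        if len(pep) >= min_peptide_len
    }


def as_tuples(orfs):
    return {(o.frame, o.start_nt, o.end_nt, o.peptide) for o in orfs}


@pytest.mark.parametrize(
    "cds,frame,expected",
    [
        ("ATGGCT", 0, "MA"),
        ("ATGTAA", 0, "M"),          # stop terminates translation
        ("AATGGCT", 1, "MA"),        # manual frame shift
        ("ATGGC", 0, "M"),           # trailing partial codon ignored
        ("", 0, ""),
    ],
)
def test_translate(cds, frame, expected):
    assert translate(cds, frame) == expected


def test_translate_rejects_bad_input():
    with pytest.raises(ValueError):
        translate("ATGN", 0)
    with pytest.raises(ValueError):
        translate("ATG", 3)


@pytest.mark.parametrize(
    "seq,min_len,expected",
    [
        ("ATGAAATAA", 1, {(0, 0, 9, "MK")}),
        ("TATGAAATAAT", 1, {(1, 1, 10, "MK")}),
        ("AAACCCGGGTTT", 1, set()),              # no ATG
        ("ATGAAACCC", 1, set()),                 # ATG without in-frame stop
        ("ATGATGAAATAA", 1, {(0, 0, 12, "MMK")}),  # 5'-most ATG per stop
    ],
)
def test_find_orfs_examples(seq, min_len, expected):
    assert as_tuples(find_orfs(seq, min_peptide_len=min_len)) == expected


def test_find_orfs_all_starts_emits_nested():
    orfs = find_orfs("ATGATGAAATAA", min_peptide_len=1, all_starts=True)
    assert as_tuples(orfs) == {(0, 0, 12, "MMK"), (0, 3, 12, "MK")}


@given(st.integers(0, 10_000))
def test_find_orfs_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(30, 600))
    seq = "".join(rng.choice(list("ACGT"), size=n))
    assert as_tuples(find_orfs(seq, min_peptide_len=1)) == brute_force_orfs(seq, 1)


def _protein(seq, gene="GENE1", pid="PROT1", tpm=None):
    return ProteinRecord(pid, gene, seq, tpm or {"tumor": 1.0, "normal": 1.0})


class TestMutanome:
    def test_interior_missense_window(self):
        prot = _protein("A" * 100)
        mut = SomaticMutation("GENE1", "missense", protein_position=50, ref_aa="A", alt_aa="W")
        entry = build_mutanome_entry(prot, mut)
        assert len(entry.sequence) == 61
        assert entry.sequence[30] == "W"  # mutated residue at window center
        assert entry.sequence.count("W") == 1

    def test_nterminal_missense_clipped(self):
        prot = _protein("A" * 100)
        mut = SomaticMutation("GENE1", "missense", protein_position=5, ref_aa="A", alt_aa="W")
        entry = build_mutanome_entry(prot, mut)
        assert len(entry.sequence) == 35  # 4 upstream + site + 30 downstream
        assert entry.sequence[4] == "W"

    def test_missense_differs_at_exactly_one_position(self):
        prot = _protein("ACDEFGHIKLMNPQRSTVWY" * 5)
        mut = SomaticMutation("GENE1", "missense", protein_position=50, ref_aa="L", alt_aa="A")
        entry = build_mutanome_entry(prot, mut)
        wild = prot.sequence[19:80]
        diffs = [i for i, (a, b) in enumerate(zip(wild, entry.sequence)) if a != b]
        assert diffs == [30]

    def test_ref_mismatch_raises(self):
        prot = _protein("A" * 100)
        mut = SomaticMutation("GENE1", "missense", protein_position=50, ref_aa="C", alt_aa="W")
        with pytest.raises(ValueError, match="mismatch"):
            build_mutanome_entry(prot, mut)

    def test_frameshift_matches_manual_translation(self):
        # 60-nt toy CDS; delete nucleotide 31 and hand-translate the shift
        cds = (
            "ATGGCTGCTGCTGCTGCTGCTGCTGCTGCT"  # M + 9x A
            "GAAGAAGAAGAAGAAGAAGAAGAAGAATAA"  # 9x E + stop
        )
        prot = _protein(translate(cds))
        mut = SomaticMutation("GENE1", "frameshift", cds_position=31, deleted=1)
        entry = build_mutanome_entry(prot, mut, cds=cds)
        shifted = cds[:30] + cds[31:]
        expected = translate(shifted)  # runs to the first new stop (or CDS end)
        aa_idx = 30 // 3
        assert entry.sequence == expected[max(0, aa_idx - 30):]
        assert entry.sequence.startswith("MAAAAAAAAA")
        # downstream of the shift the sequence no longer reads E...E
        assert "EEE" not in entry.sequence[10:]

    def test_frameshift_requires_cds(self):
        prot = _protein("A" * 50)
        mut = SomaticMutation("GENE1", "frameshift", cds_position=10, inserted="A")
        with pytest.raises(ValueError, match="CDS"):
            build_mutanome_entry(prot, mut)


class TestAssembleDatabase:
    def _herv(self, hid, tpm_tumor):
        # one clean 10-codon ORF
        seq = "CCC" + "ATG" + "GCT" * 9 + "TAA" + "GGG"
        return HervTranscript(hid, seq, {"tumor": tpm_tumor, "normal": 1.0})

    def test_tpm_zero_source_excluded(self):
        hervs = [self._herv("h1", 1.0), self._herv("h2", 0.0)]
        db = assemble_database([], [], hervs, sample="tumor")
        assert {e.provenance["source_id"] for e in db} == {"h1"}

    def test_no_mutations_no_hervs_is_expressed_canonical(self):
        prots = [
            _protein("A" * 100, "G1", "P1", {"tumor": 5.0}),
            _protein("C" * 100, "G2", "P2", {"tumor": 0.0}),
        ]
        db = assemble_database(prots, [], [], sample="tumor")
        assert [e.entry_id for e in db] == ["canonical|P1"]

    def test_herv_orf_entry_count(self):
        hervs = [self._herv("h1", 1.0), self._herv("h2", 0.0)]
        db = assemble_database([], [], hervs, sample="tumor", min_orf_aa=1)
        herv_entries = [e for e in db if e.category == CATEGORY_HERV_ORF]
        assert len(herv_entries) == 1
        assert herv_entries[0].sequence == "M" + "A" * 9

    def test_assembly_order_independent_and_idempotent(self, small_world):
        w = small_world
        args = dict(sample="tumor", cds_by_gene=w["cds_by_gene"])
        db1 = assemble_database(w["proteome"], w["mutations"], w["hervs"], **args)
        db2 = assemble_database(
            list(reversed(w["proteome"])),
            list(reversed(w["mutations"])),
            list(reversed(w["hervs"])),
            **args,
        )
        assert db1 == db2
        assert db1 == assemble_database(w["proteome"], w["mutations"], w["hervs"], **args)
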