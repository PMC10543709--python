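"""Readers and writers for the plain-text formats used by the pipeline.

FASTA via Biopython; tabular inputs/outputs as TSV via pandas; MGF-style
peak lists with a minimal reader/writer (only the handful of keys the
fragment annotator needs: PEPMASS, CHARGE, TITLE).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fragment_calc import Spectrum
from .psm_pipeline import PeptideIdentification, PsmRecord
from .search_db import HervTranscript, ProteinRecord, SearchDbEntry, SomaticMutation


# --- FASTA -----------------------------------------------------------------

def write_plain_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_protein_fasta(path: str | Path, proteins: Sequence[ProteinRecord]) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description=f"gene={p.gene_id}")
        for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_protein_fasta(
    path: str | Path, expression: Mapping[str, Mapping[str, float]] | None = None
) -> list[ProteinRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.id
        for token in rec.description.split():
            if token.startswith("gene="):
                gene = token[5:]
        tpm = dict((expression or {}).get(rec.id, {})) or dict(
            (expression or {}).get(gene, {})
        )
        out.append(ProteinRecord(rec.id, gene, str(rec.seq), tpm))
    return out


def write_herv_fasta(path: str | Path, hervs: Sequence[HervTranscript]) -> None:
    records = [SeqRecord(Seq(h.sequence), id=h.herv_id, description="") for h in hervs]
    SeqIO.write(records, str(path), "fasta")


def read_herv_fasta(
    path: str | Path, expression: Mapping[str, Mapping[str, float]] | None = None
) -> list[HervTranscript]:
    return [
        HervTranscript(rec.id, str(rec.seq), dict((expression or {}).get(rec.id, {})))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_plain_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_search_db_fasta(path: str | Path, entries: Sequence[SearchDbEntry]) -> None:
    """Structured headers: >entry_id source=... [coords=frame:start-end] [mut=...]"""
    with open(path, "w") as fh:
        for e in entries:
            parts = [e.entry_id, f"source={e.provenance.get('source_id', '')}"]
            if "frame" in e.provenance:
                parts.append(
                    f"coords={e.provenance['frame']}:"
                    f"{e.provenance['start_nt']}-{e.provenance['end_nt']}"
                )
            if "mutation" in e.provenance:
                parts.append(f"mut={e.provenance['mutation']}")
            fh.write(f">{parts[0]} {' '.join(parts[1:])}\n{e.sequence}\n")


def read_search_db_fasta(path: str | Path) -> list[SearchDbEntry]:
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        category = rec.id.split("|", 1)[0]
        provenance: dict[str, object] = {}
        for token in rec.description.split()[1:]:
            if token.startswith("source="):
                provenance["source_id"] = token[7:]
            elif token.startswith("coords="):
                frame, span = token[7:].split(":")
                start, end = span.split("-")
                provenance.update(
                    frame=int(frame), start_nt=int(start), end_nt=int(end),
                    nt_length=int(end) - int(start),
                )
            elif token.startswith("mut="):
                provenance["mutation"] = token[4:]
        entries.append(SearchDbEntry(rec.id, category, str(rec.seq), provenance))
    return entries


# --- TSV -------------------------------------------------------------------

def write_expression_tsv(
    path: str | Path,
    proteins: Sequence[ProteinRecord] = (),
    hervs: Sequence[HervTranscript] = (),
) -> None:
    rows = [
        {"id": p.id, "sample": s, "tpm": v}
        for p in proteins
        for s, v in p.tpm.items()
    ] + [
        {"id": h.herv_id, "sample": s, "tpm": v}
        for h in hervs
        for s, v in h.tpm.items()
    ]
    pd.DataFrame(rows, columns=["id", "sample", "tpm"]).to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | Path) -> dict[str, dict[str, float]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.id), {})[str(row.sample)] = float(row.tpm)
    return out


def write_mutations_tsv(path: str | Path, mutations: Sequence[SomaticMutation]) -> None:
    rows = [
        {
            "gene_id": m.gene_id, "type": m.type,
            "protein_position": m.protein_position if m.protein_position else "",
            "ref_aa": m.ref_aa or "", "alt_aa": m.alt_aa or "",
            "cds_position": m.cds_position if m.cds_position else "",
            "inserted": m.inserted, "deleted": m.deleted,
        }
        for m in mutations
    ]
    pd.DataFrame(
        rows,
        columns=[
            "gene_id", "type", "protein_position", "ref_aa", "alt_aa",
            "cds_position", "inserted", "deleted",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_mutations_tsv(path: str | Path) -> list[SomaticMutation]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        if row.type == "missense":
            out.append(
                SomaticMutation(
                    gene_id=str(row.gene_id), type="missense",
                    protein_position=int(row.protein_position),
                    ref_aa=str(row.ref_aa), alt_aa=str(row.alt_aa),
                )
            )
        else:
            out.append(
                SomaticMutation(
                    gene_id=str(row.gene_id), type="frameshift",
                    cds_position=int(row.cds_position),
                    inserted=str(row.inserted), deleted=int(row.deleted),
                )
            )
    return out


def write_psms_tsv(path: str | Path, psms: Sequence[PsmRecord]) -> None:
    pd.DataFrame(
        [
            {
                "peptide": p.peptide, "score": p.score, "is_decoy": int(p.is_decoy),
                "sample": p.sample, "charge": p.charge, "mods": p.modifications,
            }
            for p in psms
        ],
        columns=["peptide", "score", "is_decoy", "sample", "charge", "mods"],
    ).to_csv(path, sep="\t", index=False)


def read_psms_tsv(path: str | Path) -> list[PsmRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        PsmRecord(
            peptide=str(row.peptide), score=float(row.score),
            is_decoy=bool(int(row.is_decoy)), sample=str(row.sample),
            charge=int(row.charge), modifications=str(row.mods),
        )
        for row in df.itertuples(index=False)
    ]


def write_identifications_tsv(
    path: str | Path, identifications: Sequence[PeptideIdentification]
) -> None:
    pd.DataFrame(
        [
            {
                "peptide": i.peptide, "q_value": i.q_value, "length": i.length,
                "samples": ",".join(sorted(i.samples_detected)),
                "category": i.category or "", "source_id": i.source_assigned or "",
            }
            for i in identifications
        ],
        columns=["peptide", "q_value", "length", "samples", "category", "source_id"],
    ).to_csv(path, sep="\t", index=False)


def read_identifications_tsv(path: str | Path) -> list[PeptideIdentification]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        PeptideIdentification(
            peptide=str(row.peptide), best_score=float("nan"),
            q_value=float(row.q_value),
            samples_detected=frozenset(str(row.samples).split(",")) if row.samples else frozenset(),
            category=str(row.category) or None,
            source_assigned=str(row.source_id) or None,
        )
        for row in df.itertuples(index=False)
    ]


# --- MGF -------------------------------------------------------------------

def write_mgf(path: str | Path, spectra: Iterable[tuple[str, Spectrum]]) -> None:
    with open(path, "w") as fh:
        for title, spec in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={title}\n")
            fh.write(f"PEPMASS={spec.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={spec.charge}+\n")
            for mz, inten in spec.peaks:
                fh.write(f"{mz:.6f} {inten:.2f}\n")
            fh.write("END IONS\n")


def read_mgf(path: str | Path) -> list[tuple[str, Spectrum]]:
    spectra = []
    title, pepmass, charge, peaks = "", 0.0, 1, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line == "BEGIN IONS":
                title, pepmass, charge, peaks = "", 0.0, 1, []
            elif line == "END IONS":
                spectra.append((title, Spectrum(tuple(peaks), pepmass, charge)))
            elif line.startswith("TITLE="):
                title = line[6:]
            elif line.startswith("PEPMASS="):
                pepmass = float(line[8:].split()[0])
            elif line.startswith("CHARGE="):
                charge = int(line[7:].rstrip("+-"))
            elif line and line[0].isdigit():
                mz, inten = line.split()[:2]
                peaks.append((float(mz), float(inten)))
    return spectra
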