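"""End-to-end driver: synthetic experiment -> ranked candidate antigens.

Chains the whole discovery procedure on a simulated tumor/normal pair:
per-sample search-database assembly, PSM collapse and peptide-level
q-values, detection filtering, novelty/category/source annotation, binder
prediction, tumor-exclusivity and expression fold change, ΔΔCt
confirmation, and final candidate ranking.  Used by the tests, the
acceptance script and the ``run`` CLI subcommand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import synthetic_data as sim
from .peptidome_stats import PositionWeightPredictor, predict_binders
from .psm_pipeline import (
    DbIndex,
    PeptideIdentification,
    annotate_identifications,
    check_novelty,
    collapse_to_peptides,
    compute_qvalues,
    filter_identifications,
)
from .search_db import CATEGORY_HERV_ORF, SearchDbEntry, assemble_database
from .synthetic_data import NORMAL, TUMOR, SimConfig
from .tumor_assoc import (
    CandidateAntigen,
    ExpressionRecord,
    VennPartition,
    ddct_fold_change,
    exclusivity_venn,
    rank_candidates,
)


@dataclass
class PipelineResult:
    config: SimConfig
    identifications: dict[str, list[PeptideIdentification]]
    search_db: dict[str, list[SearchDbEntry]]
    venn: VennPartition
    expression: dict[str, ExpressionRecord]
    candidates: list[CandidateAntigen]
    ddct_fc: pd.Series
    truth: sim.SimulatedPsms
    accepted_labels: dict[str, bool]  # accepted peptide -> was a true peptide

    @property
    def top_candidate(self) -> CandidateAntigen | None:
        passed = [c for c in self.candidates if c.passed]
        return passed[0] if passed else None

    def realized_fdp(self, sample: str | None = None) -> float:
        """False-discovery proportion among accepted peptides.

        With ``sample`` the FDP of that sample's analysis (the quantity the
        q-value threshold controls); without, the FDP of the union of
        accepted peptides across samples, which runs slightly higher than
        nominal because true peptides deduplicate across samples more often
        than false ones.
        """
        if sample is not None:
            idents = self.identifications[sample]
            if not idents:
                return 0.0
            n_false = sum(
                1 for i in idents if i.peptide not in self.truth.true_peptides
            )
            return n_false / len(idents)
        if not self.accepted_labels:
            return 0.0
        n_false = sum(1 for true in self.accepted_labels.values() if not true)
        return n_false / len(self.accepted_labels)


def run_pipeline(
    config: SimConfig,
    q_max: float = 0.01,
    min_fc: float = 2.0,
    max_rank: float = 0.5,
) -> PipelineResult:
    """Run the full discovery procedure on one simulated patient."""
    proteome = sim.generate_proteome(config)
    hervs = sim.generate_hervs(config)
    mutations, cds_by_gene = sim.generate_mutations(config, proteome)
    dbs = {
        s: assemble_database(
            proteome, mutations, hervs, sample=s, cds_by_gene=cds_by_gene
        )
        for s in (TUMOR, NORMAL)
    }
    simulated = sim.generate_psms(config, dbs)

    herv_tpm = {h.herv_id: dict(h.tpm) for h in hervs}
    canonical_seqs = [p.sequence for p in proteome]
    identifications: dict[str, list[PeptideIdentification]] = {}
    accepted_labels: dict[str, bool] = {}
    for sample in (TUMOR, NORMAL):
        psms = [p for p in simulated.psms if p.sample == sample]
        collapsed = collapse_to_peptides(psms)
        qvals = compute_qvalues(collapsed)
        idents = filter_identifications(collapsed, qvals, q_max=q_max)
        index = DbIndex(dbs[sample])
        idents = annotate_identifications(idents, index, herv_tpm, sample)
        # hERV calls must survive the isobaric novelty check
        idents = [
            i
            for i in idents
            if i.category != CATEGORY_HERV_ORF
            or check_novelty(i.peptide, [canonical_seqs])
        ]
        identifications[sample] = idents
        for i in idents:
            accepted_labels[i.peptide] = (
                accepted_labels.get(i.peptide, False)
                or i.peptide in simulated.true_peptides
            )

    herv_idents = {
        s: {i.peptide for i in identifications[s] if i.category == CATEGORY_HERV_ORF}
        for s in (TUMOR, NORMAL)
    }
    venn = exclusivity_venn(herv_idents[TUMOR], herv_idents[NORMAL])

    expression = {
        h.herv_id: ExpressionRecord(
            h.herv_id, h.tpm.get(TUMOR, 0.0), h.tpm.get(NORMAL, 0.0)
        )
        for h in hervs
    }
    herv_peptides = sorted(herv_idents[TUMOR] | herv_idents[NORMAL])
    predictor = PositionWeightPredictor()
    binder_ranks = {b.peptide: b.percentile_rank for b in predict_binders(herv_peptides, predictor)}

    candidates = rank_candidates(
        identifications[TUMOR],
        venn,
        expression,
        binder_ranks,
        min_fc=min_fc,
        max_rank=max_rank,
    )

    ct = sim.generate_ct_table(config)
    fc = ddct_fold_change(
        ct,
        target_gene=config.planted_herv_id,
        reference_gene=config.reference_gene,
        calibrator_sample=NORMAL,
    )

    return PipelineResult(
        config=config,
        identifications=identifications,
        search_db=dbs,
        venn=venn,
        expression=expression,
        candidates=candidates,
        ddct_fc=fc,
        truth=simulated,
        accepted_labels=accepted_labels,
    )
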