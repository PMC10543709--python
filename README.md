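# hervantigen

Proteogenomic discovery of tumor-associated human endogenous retrovirus
(hERV) antigens from HLA class I immunopeptidome data.

## The problem

Renal cell carcinoma responds to immune checkpoint blockade despite a low
mutation burden, and one proposed explanation is CD8+ T cell surveillance
of peptides translated from reactivated endogenous retroviruses. Such
peptides are invisible to a standard MS database search because they are
not in UniProt/RefSeq: finding them requires a *personalized* search
space built from the patient's own genomic and transcriptomic data, and a
downstream procedure that separates genuinely tumor-associated hERV
ligands from ones equally presented by normal tissue.

`hervantigen` implements that procedure as a tested, reusable library +
CLI for computational immunologists:

1. **Search-database construction** (`search_db`) — the union of
   (a) expressed canonical protein sequences, (b) *mutanome* windows
   (±30 residues around each somatic missense site; frameshift windows
   translated in the shifted frame to the first novel stop), and
   (c) three-frame ATG→stop ORF translations of expressed hERV
   transcripts. Sources with TPM ≤ 0 in the analyzed sample are excluded.
2. **PSM validation** (`psm_pipeline`) — peptide-level concatenated
   target-decoy q-values, FDR̂(t) = #decoys≥t / #targets≥t with
   q(s) = min_{t≤s} FDR̂(t); detection threshold q ≤ 0.01 and lengths
   8–12; Leu/Ile-isobaric novelty checking against canonical proteomes;
   category assignment with precedence canonical > mutanome > hERV-ORF;
   source-hERV disambiguation by highest expression.
3. **Fragment arithmetic** (`fragment_calc`) — monoisotopic b/y ion
   series (b_i + y_{n−i} = M + 2·1.007276), Met-oxidation (+15.994915 Da),
   tolerance-based spectrum annotation (0.02 Da fragment / 10 ppm
   precursor) and endogenous-vs-synthetic spectrum comparison.
4. **Peptidome statistics** (`peptidome_stats`) — length distributions,
   9-mer anchor position-frequency matrices with information content,
   percentile-rank binder summaries (strong < 0.5, weak < 2.0) through a
   pluggable predictor, hERV fraction, source-ORF length comparisons.
5. **Tumor association** (`tumor_assoc`) — tumor/normal exclusivity,
   hERV expression fold change, qPCR ΔΔCt (FC = 2^(−ΔΔCt)), cross-patient
   sequence sharing, and final candidate ranking.
6. **Synthetic data** (`synthetic_data`) — a seeded generator of every
   input with planted ground truth: a tumor-overexpressed hERV (default
   7.7-fold) carrying an HLA-A24-motif 9-mer at the 3′ end of a short
   cryptic ORF, 322 missense + 14 frameshift mutations, and
   target/decoy/false-target PSM score distributions with known labels.

## Worked example

```python
from hervantigen import SimConfig, run_pipeline

result = run_pipeline(SimConfig(seed=1))
print(result.venn.sizes)           # (1, 3, 3)  tumor-only / shared / normal-only hERV peptides
top = result.top_candidate
print(top.peptide, top.source_herv)          # LYDTVTHTF hERV3895
print(round(top.expression_fc, 3))           # 7.634
print(round(float(result.ddct_fc['tumor']), 3))  # 7.745
```

The simulated patient yields ~585 validated tumor peptides at q ≤ 0.01;
among the hERV-ORF peptides, the planted antigen `LYDTVTHTF` is the only
one that passes all three gates (tumor-exclusive, source hERV
overexpressed ≥ 2-fold, percentile rank < 0.5), its RNA-seq fold change
(7.63, pseudocount 0.01) matches the planted 7.7-fold effect, and the
qPCR ΔΔCt readout independently recovers 7.75-fold.

The same flow is available from the shell:

```sh
hervantigen simulate --seed 1 --outdir sim/
hervantigen build-db --canonical sim/canonical.fasta --hervs sim/hervs.fasta \
    --expression sim/expression.tsv --mutations sim/mutations.tsv \
    --cds sim/mutated_cds.fasta --sample tumor -o db_tumor.fasta
hervantigen process-psms --psms sim/psms.tsv --db db_tumor.fasta \
    --canonical sim/canonical.fasta --expression sim/expression.tsv \
    --sample tumor -o ids_tumor.tsv
hervantigen fragments --peptide LYDTVTHTF
```

## Acceptance script

`scripts/acceptance.py` re-runs the whole discovery procedure from
scratch on the seeded synthetic experiment and writes its results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It prints a run summary (identification counts, hERV exclusivity
partition, top-ranked candidate with its fold change, ΔΔCt readout and
realized false-discovery proportion).

See `docs/methods.md` for the model, parameter defaults, numerical
choices and known limitations.
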