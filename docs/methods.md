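# Methods

## Scope and model

`hervantigen` models the computational core of a proteogenomic HLA
class I ligandome study of paired tumor/normal tissue: construct a
personalized search space, validate peptide-spectrum matches at a
peptide-level FDR, isolate the noncanonical (hERV-ORF-derived) subset,
and rank those peptides by tumor association. Everything upstream of the
PSM list (instrument control, raw-spectrum search engines, read
alignment, variant calling, expression quantification) is treated as an
input; a declared stand-in scorer and a seeded synthetic-data layer make
the whole procedure testable without any external download.

## Search space

The database is the union of three categories, assembled per sample:

* **canonical** — protein sequences of transcripts with TPM > 0 in the
  analyzed sample (threshold configurable).
* **mutanome** — for each missense mutation, the window from 30 residues
  upstream to 30 residues downstream of the mutated site (clipped at the
  protein ends) with the alternate residue substituted; for each
  frameshift, 30 residues upstream of the first altered codon followed by
  the shifted-frame translation to the first novel stop (or CDS end if no
  stop is reached). Interior missense windows are therefore 61-mers with
  the variant at offset 30.
* **herv_orf** — forward-strand, three-frame ATG→stop ORFs of expressed
  hERV transcripts, one ORF per (frame, stop) anchored at the 5′-most ATG
  since the previous in-frame stop (`all_starts` emits every nested ATG).
  ORFs without an in-frame stop are excluded; the minimum translated
  length defaults to 8 residues, the shortest reportable ligand.
  Reverse-strand scanning is deliberately off by default.

Coordinates are 0-based half-open internally; ORF nucleotide lengths
include the stop codon.

## Peptide validation

PSMs are collapsed to one row per (peptide, decoy-status) keeping the
best score and the union of samples; modification strings are ignored for
identity. q-values use the simplest concatenated target-decoy estimator,
FDR̂(t) = #decoys≥t / #targets≥t, monotonized as q(s) = min over
thresholds t ≤ s, capped at 1. The +1 numerator correction is available
(`plus_one=True`) but off by default; without it the estimator is mildly
anticonservative — in the default simulation the realized per-analysis
false-discovery proportion at q ≤ 0.01 averages ≈ 0.011–0.015, within the
per-analysis binomial band. Note that the FDP of the *union* of accepted
peptides across the tumor and normal analyses runs higher than the
per-analysis value, because true peptides deduplicate across samples more
often than false ones do; calibration claims are therefore per analysis.

Detection requires q ≤ 0.01 and length 8–12. hERV-ORF calls must also
pass the novelty check: because MS cannot distinguish Leu from Ile, a
peptide is novel only if *no* L/I variant occurs in any canonical
proteome. The default expansion is combinatorial over all L/I sites
(capped at 12 sites = 4,096 variants, error beyond); `swap_all` checks
only the original plus the single all-swapped sequence. Category
assignment uses the precedence canonical > mutanome > herv_orf, so a
peptide explainable canonically is never called noncanonical. When an
hERV peptide occurs in ORFs of several hERVs, the one with the highest
TPM in the analyzed sample is assigned as source (ties break
lexicographically).

## Mass arithmetic

Monoisotopic residue masses throughout; water 18.010565 Da, proton
1.007276 Da, Met-oxidation +15.994915 Da per site. Only singly-charged
b/y series are generated by default (charge 1–4 supported), matching the
ion types annotated in HLA-ligand HCD spectra. Spectrum matching is
greedy nearest-peak with each observed peak usable once, fragment
tolerance 0.02 Da, precursor tolerance 10 ppm (flagged, not fatal).
Spectrum similarity is the Jaccard index of matched ion-label sets of two
spectra annotated against the same theoretical series — a label-level
metric, chosen because the validation question is "are the same ions
present", not "do intensities agree". The stand-in PSM scorer sums
log(1 + intensity) over matched ions; it is deterministic and makes no
claim of emulating any commercial engine's statistics.

## Binder prediction

External predictors (e.g. a NetMHCpan wrapper) plug in as any callable
peptide → percentile rank in [0, 100]; classes use the conventional
thresholds (strong < 0.5, weak < 2.0). The built-in predictor is a
position-weight scorer over an HLA-A24-like anchor profile — Tyr (+4.0)
and Phe (+1.5) at position 2; Phe/Leu/Ile (+3.0/+2.7/+2.4) at the C
terminus — plus Normal(0, 0.05) per-(position, residue) jitter from a
fixed internal seed so scores are effectively continuous. Ranks are
calibrated per length against a fixed seeded background of 100,000 random
peptides (fraction scoring strictly better), which makes ranks uniform on
random peptides and exchangeable with external predictors' ranks. It is a
toy: it encodes only the two canonical A24 anchors and must not be used
for real epitope selection.

## Tumor association

Detection is defined on the post-FDR identification list per sample, and
hERV peptides are partitioned into tumor-only / shared / normal-only.
Expression fold change is (TPM_tumor + ε)/(TPM_normal + ε) with
ε = 0.01 TPM to keep silent hERVs finite. Candidates must be
tumor-exclusive, have source fold change ≥ `min_fc` (default 2; set to 1
to disable — the underlying study applied a qualitative contrast, so the
numeric gate is this package's choice) and percentile rank < 0.5;
passing candidates are ordered by (fold change desc, rank asc), and
failing peptides are reported with explicit reasons. qPCR confirmation
uses ΔΔCt: replicate Ct values are arithmetically averaged, ΔCt = target
− reference per sample, ΔΔCt is relative to a calibrator sample, and
FC = 2^(−ΔΔCt) with the calibrator pinned at exactly 1. Cross-patient
sharing is by exact sequence identity (no L/I expansion): the question is
whether the identical reported ligand recurs.

## Synthetic experiment

The generator's defaults are the stated world of a single-patient
tumor/normal study:

| parameter | default | rationale |
|---|---|---|
| proteins | 250 × 100–400 aa | desk-scale canonical space, all TPM > 0 |
| hERVs | 40 × 600–2,000 nt | each with ≥ 1 embedded ORF; ~15% silent in one sample |
| planted antigen | `LYDTVTHTF` (9-mer, Y at P2, F at C-term) | A24 anchor motif |
| planted hERV | `hERV3895`, tumor/normal FC 7.7 | headline effect size |
| mutations | 322 missense + 14 frameshift | reported mutation burden |
| target PSMs / true peptides | 2,300 / 1,300 | ≈ reported nonredundant peptidome scale |
| hERV true peptides | 8 | reported hERV ligand count |
| false targets / decoys | 1,000 / 1,000 | matched 1:1 (see below) |
| scores | true N(4.5, 1), false & decoy N(0, 1) | well-separated stand-in; the real engine's score law is unknown |
| acquisition | m/z 350–2,000, charge 1+–4+ | printed instrument settings |

The planted transcript is built as: random 5′ region, an upstream decoy
ORF (so the antigen ORF is not the transcript's first), a spacer, then
`TAA·ATG·(8–20 random non-stop codons)·(antigen codons)·TGA` — the
in-frame TAA pins the ORF start, and the antigen occupies the ORF's 3′
end, 17–30 residues total. Back-translation picks uniformly among
synonymous codons. The antigen and *all* its L/I-isobaric variants are
kept out of the random canonical proteome by redrawing any colliding
protein, so ground-truth novelty is exact.

True-target peptides are windows of database sequences with 9-mer-
dominated lengths (60% 9-mers) and anchor bias (70% Tyr at P2, 80%
F/L/I C-term) imposed by rejection sampling, so they remain genuine
substrings of the search space. False targets are unbiased database
windows scored like decoys: a real concatenated search assigns wrong but
in-database peptides to junk spectra. Decoys are reversals of freshly
sampled windows rather than of resampled true peptides — reversing draws
from the true pool would give decoy peptides a different collapse
multiplicity than the false targets they must estimate, and measurably
biases the FDR estimate low. `n_false_target_psms` defaults equal to
`n_decoy_psms`, the exchangeability assumption under which the decoy
count estimates the false-target count.

What the generator does **not** model: raw spectra for the main PSM flow
(scores are drawn, not computed), chimeric spectra, retention time,
intensity structure, shared peptides between hERV families, expression
estimation noise, or inter-patient variability. A green end-to-end test
therefore establishes that the *procedure* recovers a planted signal
under its own assumptions — not that the stand-in scorer or toy predictor
would perform on real data.

## Numerical choices

* Ties in q-value thresholds are handled by evaluating FDR̂ at every
  observed score and taking suffix minima; equal scores share a q-value.
* Percentile ranks use strict "scored better" counts, so a peptide above
  the whole background has rank exactly 0.
* Reported percentages round half-up to one decimal.
* ΔΔCt requires the reference gene in every sample and errors otherwise.
* All generator streams derive from `(seed, stream-id)` so adding a
  generator never perturbs another's output; the predictor's calibration
  seed is a fixed constant independent of the user seed.

## Known limitations

* The worked-example ligand inventories reproduce published *counts*;
  five of the eight first-patient sequences and three of five
  second-patient sequences are synthetic stand-ins (marked as such),
  because the underlying per-peptide tables are not machine-readable.
* The built-in predictor's 73%-strong-binder figure on real A24
  ligandomes is not reproducible here; only relative statements (motif
  set vs random set) are tested.
* Frameshift CDSs are back-translated from protein sequence, so codon
  usage is uniform rather than human-like.
* The q-value estimator assumes exchangeable decoys; with very few
  decoys above threshold (≪ 10) its variance is large and the +1
  correction is advisable.
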