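# Methods

## Study design being modeled

The pipeline targets pooled (replicate-free) small-RNA sequencing studies of
the kind used to survey drought-responsive miRNAs in sugarcane: two
genotypes of contrasting drought tolerance (labels HT/LT), irrigated vs
drought conditions, two time points — eight libraries, each a single pool.
Because libraries are pools, differential expression is a two-library count
comparison, not a replicate-based dispersion model; the exact
Audic–Claverie test is the appropriate tool and is what this package
implements.

## Preprocessing

Reads are modeled as insert + 3' adapter. Trimming removes the longest read
suffix matching an adapter prefix (≥ 6 nt overlap) or everything from an
internal full-adapter occurrence. Reads containing N are discarded before
collapsing: every downstream stage (mapping, homology, target scoring) does
per-position mismatch accounting, and an ambiguous base has no defined
mismatch status. Length bounds are separate knobs: the gel-selection window
(16–27 nt) and the analysis floor (18 nt) both exist in this protocol
family; defaults retain 18–27 nt. Sequences are stored as DNA and rendered
as RNA only in reports.

## Annotation classification

Unique reads are assigned to the first category in a precedence order with
an exact, full-length substring match (reverse complement for the antisense
exon category): rRNA > tRNA > snRNA > snoRNA > miRNA > siRNA > sense exon >
antisense exon > unannotated. Structural-RNA categories outrank miRNA so
rRNA/tRNA fragments can never inflate miRNA counts; the order is
configurable. Matching uses a 16-mer seed index over the annotation
sequences plus verification, so classifying 10⁵–10⁶ unique reads stays
fast. Classification is a partition: category totals must sum exactly to
the library size N, and the pipeline asserts this on every run.

## Mapping

A k-mer index (default k = 12, k ≥ 8) over the forward strand supports
mismatch-bounded placement by pigeonhole seeding: with budget m, one of
m + 1 non-overlapping seeds must be exact. When a read is too short for
m + 1 seeds (e.g. 18 nt at m = 2), placement falls back to a vectorized
exhaustive scan, so hit sets are complete at every budget — a property the
suite checks against a brute-force oracle. Default budget is 0 mismatches
(the discovery convention this pipeline family inherits; the published
2-mismatch allowance belongs to homology naming, not mapping). Reads with
more than 15 placements are treated as multi-mapped and excluded from
precursor nomination. Coordinates are 0-based half-open internally, 1-based
inclusive in reports.

## Folding and precursor criteria

Candidate windows (250 nt, centered on the mapped read, truncated at
reference ends, reverse-complemented for minus-strand loci) are folded by a
Nussinov-style dynamic program minimizing additive pair energies: G-C −3.0,
A-U −2.0, G-U −1.0 (model kcal/mol), minimum hairpin loop 3, no
pseudoknots. Traceback is deterministic: pairing (i, j) beats bifurcation,
and the smallest split point wins. This model is deliberately not a
nearest-neighbor thermodynamic model: it is exactly verifiable against
exhaustive enumeration at desk scale, which the test suite does for ≥ 200
random sequences ≤ 18 nt. The cost is that its MFE values are comparable
only within the model — published absolute MFEs (computed with full
nearest-neighbor folders) are out of reach, and no test asserts them. An
external folder honoring the `fold(seq) -> (dot-bracket, MFE)` contract can
be slotted in where published-grade energies matter.

The four acceptance criteria for a precursor candidate:

1. **stem-loop with the mature in one arm** — operationalized as: ≥ 60% of
   mature positions paired, no mature position paired within the mature
   span (no crossing of the terminal loop), all partners on one side, and
   partners of successive mature positions strictly decreasing (a single
   nested ladder through one loop);
2. **star compatibility** — at most 6 mature positions unpaired against the
   opposite arm; the star span is the partner range extended by the 2 nt 3'
   overhang of the mature/star duplex;
3. **MFE < 0**;
4. **G/C content within 30–70%** of the window.

Criteria are individually switchable; the verdict is their conjunction and
every violated criterion is reported.

## Differential expression

TPM = count × 10⁶ / N with N the retained-read total. The Audic–Claverie
kernel p(y|x) is a negative binomial in y with x + 1 successes and success
probability N1/(N1 + N2); tails are accumulated in log space from log-gamma
terms, which the suite verifies to 1e-9 relative error against
arbitrary-precision summation (typical agreement ~1e-13). The two-sided
p-value doubles the smaller tail and caps at 1.

One property sometimes attributed to this test — exact invariance under
swapping (x, N1) with (y, N2) — does **not** hold for the conditional
kernel: p(0,1,n,n) = 1.0 while p(1,0,n,n) = 0.5, and tail probabilities can
differ by tens of percent in deep tails. The test is only asymptotically
symmetric. The suite therefore asserts the invariances that are exact:
dependence on library sizes only through their ratio, and p = 1 for equal
counts in equal libraries.

Signed fold change maps the treated/control ratio r to r (r ≥ 1) or −1/r
(r < 1). A contrast is significant iff |FC| > 2.00 strictly and p < 0.05.
Zero handling: the count test is defined at zero and uses raw zeros; a
fold change with one zero side carries an infinity sentinel and is never
flagged significant (an optional pseudo-TPM floor can re-admit such rows);
both sides zero is undefined and flagged. No multiple-testing correction is
applied by default (per-miRNA p < 0.05 is this literature's convention);
rounding to 2 decimals happens only at report time, half-up.

## Target prediction

Ungapped antiparallel scan of sense-strand transcripts. Expectation
penalties: Watson–Crick 0, G:U wobble 0.5, mismatch 1.0, doubled at miRNA
positions 2–13 (seed region); gap penalty 2.0 is reserved for the gapped
variant. Default reporting threshold e_max = 3.0 (configurable to 5).
Inhibition call: translational inhibition iff any non-Watson–Crick position
falls at miRNA positions 9–11, else cleavage. Target-site accessibility
energies (UPE) require a partition-function model and are not computed.
Transcript sense strands are taken as given from the input FASTA.

## Synthetic data generator

The generator defines the conditions under which the pipeline's statistical
guarantees are tested.

* **Genome** — each planted precursor is a designed hairpin: the
  mature/star duplex (star = exact reverse complement) sits atop a ~94 bp
  random lower stem, flanked by low-pairing A/C spacers (120 nt). The long
  designed stem is needed because, under an additive pair-energy model,
  a short hairpin surrounded by generic random sequence is energy-tied with
  structures that pair the duplex bases into the flanks. Every planted
  window is verified against `evaluate_precursor` during generation, with
  flank regeneration on an unlucky draw: criteria passage is a construction
  invariant. Window G/C lands near 50%.
* **Matures** — derived from a curated sorghum-homolog reference set by 0–2
  substitutions, constrained to be (a) within 2 mismatches of exactly one
  reference name and (b) pairwise distinct (two loci sharing one sequence
  would pool counts and dilute their planted fold changes).
* **Libraries** — reads are insert + 3' adapter clipped to 36 nt, constant
  quality. Per-miRNA counts are Poisson with mean depth × baseline/10⁶ ×
  fold-change (negative binomial with stated dispersion available as a
  robustness knob); baselines are log-uniform on 400–4000 TPM, reflecting
  that drought-responsive plant miRNAs are moderately-to-highly expressed.
  Planted drought/irrigated ratios cycle through
  (1, 4, ¼, 1, 3, ⅓, 1, 2, ½, 1): about a third null, with |FC| ≥ 3
  responders whose direction the end-to-end test must always recover.
  Decoy-category reads are drawn at 25% of depth (siRNA decoys are whole
  24-mers, giving the secondary 24 nt length mode); uniform-random
  unannotated background at 50% of depth with a 21 nt primary mode.
* **Transcriptome** — one target site per planted miRNA (up to 8), embedded
  at a recorded 1-based span in its own transcript, with a planted layout:
  perfect, one non-seed mismatch (E = 1.0), or one non-seed wobble
  (E = 0.5), defects placed outside both the seed (2–13) and central
  (9–11) spans.

What the generator does **not** model: sequencing errors, quality-score
variation, genotype sequence divergence (genotype is a label only), 5'
adapters (reads are sequenced from the insert start), and real secondary
structure statistics of plant genomes. Passing tests therefore demonstrate
correctness of the pipeline's logic and calibration of its statistics under
clean sampling assumptions, not robustness to platform noise.

## Problem sizes used in validation

Validation workloads are sized for interactive iteration: the end-to-end
study uses 30 precursors and four libraries of 2×10⁵ reads; null
calibration uses 200 replicate contrasts of 30 miRNAs at 10⁵ depth through
the count model; the power check uses 100 seeds at 200 TPM baseline and
4-fold change; mapper/folding oracles use 50 kb references and 200 short
sequences. At these sizes the full suite runs in well under a minute per
heavy test.

## Known limitations

* MFE values are model units, not thermodynamic free energies.
* The "characteristic stem-loop" reading (60% pairing, single-ladder rule)
  is one of several defensible operationalizations; it is strict about
  multi-loop arrangements.
* Homology naming reports cross-family ties as ambiguous rather than
  resolving them.
* The expectation scheme's seed span (2–13) is fixed; published scores
  produced with other seed readings can differ for seed-adjacent defects.
* SAM output is not emitted (TSV/GFF3 suffice at these scales).
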