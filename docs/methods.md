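# Methods

## Motif definition and proteome indexing

A TCEM is the five-residue stretch of an HLA-I epitope in contact with the
TCR CDR3 region: 1-based positions 4–8 of a 9-mer, 5–9 of a 10-mer. The
motif space is the 20^5 = 3,200,000 pentamers over the standard amino-acid
alphabet. A motif's *frequency* in a proteome is the number of overlapping
9-mer windows whose positions 4–8 equal the motif — an occurrence therefore
requires at least three residues upstream and one downstream within the same
protein; a terminal 5-mer substring without that context does not count.
Windows containing any non-standard letter (X, U, B, Z, …) are skipped and
counted for audit. Duplicate protein identifiers are an error; identical
sequences under different identifiers are each counted (reference proteomes
legitimately contain near-duplicate entries). Proteomes are only ever
decomposed into 9-mers; the 10-mer rule applies to epitope peptides.
Coordinates in all outputs are 1-based and fully closed.

Motifs occurring fewer than four times are classified *rare*; the boundary
is strict (count 3 → rare, count 4 → nonrare), following the observation
that such motifs are unlikely to be presented on the cell surface at all.

## cTEC expression of a motif

Raw cTEC RNA-seq counts are normalized with trimmed-mean-of-M-values (TMM)
scale factors: reference sample chosen by the 75th count-fraction
percentile closest to the mean, 30% two-sided trim on log-ratios, 5% on
average intensity, precision weights from the asymptotic binomial variance,
factors geometric-mean-centered. The implementation is cross-checked in the
test suite against Bioconductor edgeR's `calcNormFactors` (agreement to
1e-6), which serves only as an oracle. RPKM uses effective library sizes
(raw library × TMM factor): `count / (exon_kb) / (effective_library / 1e6)`;
per-gene expression is the median RPKM across cTEC samples.

Proteins join to genes through shared gene symbols (a protein maps to every
gene sharing at least one symbol; unmapped proteins are reported, not
fatal). A motif's expression is the median over one value per proteome
occurrence — a motif appearing k times in one protein contributes its
gene's median RPKM k times, and a protein mapped to several genes
contributes one value per gene per occurrence. Motifs whose occurrences all
fall in unmapped proteins have undefined expression: they are excluded from
expression-stratified analyses but retained for frequency and cleavage
analyses, and for np classification they default to "low expression" (a
motif that cannot be shown expressed in cTECs cannot be credited with
mediating positive selection); both behaviors are switchable.

Expression stratification uses tertiles (low: below the 1/3 quantile; high:
at or above the 2/3 quantile) or percentile ranks (average ranks for ties,
rank/n). The low/high boundaries for odds-ratio calculations default to the
tertile boundaries since no other cutoff is specified anywhere; they are
exposed as configuration. Housekeeping status of a motif defaults to the
*any*-encoding-gene rule (weakest sufficient definition for an enrichment
claim), with `majority` and `all` switches.

## Proteasomal cleavage cascade

From published amino-acid prevalences at the five flank positions on each
side of observed cleavage sites (i ∈ {−5…−1, +1…+5}) and the substrate
background composition:

1. preference scores `c(i, j) = prevalence(i, j) / background(j)`;
2. per inter-residue site, `C = median` of the applicable c values —
   position −1 is the residue immediately N-terminal of the site, +1 the
   residue immediately C-terminal; sites within five residues of a terminus
   use the available positions only (at least one required), because the
   source data define no exclusion rule and discarding terminal sites would
   be the more destructive reading (a require-full-context switch exists);
3. per 9-mer window starting at residue p, the formation score
   `C̄ = (C[p−1] + C[p+8]) / 2` over the two sites that must be cleaved to
   excise the peptide; the first and last windows of a protein lack an
   interior flanking site and are excluded by default (a protein terminus
   needs no cleavage, so assigning it a cleavage probability is unfounded) —
   a `terminus-one` mode substitutes C = 1 instead;
4. per motif, the median C̄ over all windows exposing it, computed
   separately for the thymo- and immunoproteasome tables (the cascade is
   identical; only the input table differs).

Uniform preference tables propagate to every motif score being exactly 1 —
the cascade's invariant, asserted end to end in the tests. Quantiles
throughout use linear interpolation (type 7); "low cleavage" means strictly
below the first quartile, so a score equal to Q1 is normal.

## Dataset curation

Assay records are filtered to 9/10-mer, standard-letter, nonhuman peptides
(decided by the taxonomy column, not sequence similarity) tested against
4-digit HLA-I alleles. Allele–peptide pairs with solely negative T-cell
assays are nonimmunogenic; with strictly more positives than negatives,
immunogenic; anything else is excluded, as are all pairs of a peptide
labelled oppositely for different alleles.

Dataset 1 keeps pairs whose predicted binding passes affinity < 500 nM OR
rank percentile < 2% (strict inequalities). Dataset 2 requires at least two
MHC-binding assays with strictly more than 60% positive and at least two
T-cell assays, then removes redundancy iteratively: the k-tuple distance
(k = 1 by default; `d = 1 − shared k-mers / (min length − k + 1)`, multiset
intersection) is computed for all pairs; among members of the
minimum-distance pair(s) the peptide with the lowest mean distance to all
remaining peptides is removed (ties broken by lexicographically smallest
sequence, one removal per iteration) until all pairwise distances are at
least 0.5 — which corresponds to a maximum 50% residue overlap under this
distance. The external alignment tool originally used for the distance is
not invoked; the reimplementation is declared, not claimed bit-identical.
Peptides in both datasets are kept only in dataset 2.

Secondary-anchor exclusion: per allele and peptide length, a position is an
anchor if the positional amino-acid entropy of bound peptides is below 0.8
**nats** (natural log; at that threshold a position is dominated by roughly
two residues — the log base is not standardized anywhere, so a bits switch
exists), requiring at least 20 bound peptides. A peptide is excluded iff
every allele it binds has an anchor inside its TCEM window.

## Similarity and cross-reactivity

Similarity between equal-length sequences is the symmetric geometric-mean
normalization `sim(a,b) = s(a,b) / √(s(a,a) · s(b,b))` of summed per-position
BLOSUM62 entries, giving sim ≤ 1 with equality iff identical (this holds
because every BLOSUM62 diagonal entry is maximal in its row, asserted at
import). The normalization is pluggable since min-based denominators exist
in the literature and would shift cutoff values. Best-hit self-similarity
against a proteome is an exhaustive equal-length ungapped scan — strictly
more sensitive than a heuristic aligner, and checked against a naive double
loop in the tests. Full 9-mers are scanned for self-similarity analyses;
cross-reactivity analyses operate on 5-mer TCEMs; one scorer serves both.

TCR cross-reactivity is estimated from single-position mutational scans:
variants with relative binding below 10% of the original epitope's are
nonbinders (≥ 10% is a binder — the boundary is inclusive), the ROC of TCEM
similarity against that label is computed with grouped ties, and the
cutpoint maximizes `Se − m·(1−Sp)` with slope
`m = cost_ratio · (1−prevalence)/prevalence` over observed scores (smallest
maximizing cutoff on ties; cost ratio 1 and sample prevalence by default,
which reduces to Youden's J at prevalence 0.5). The group-against-group
scan streams one group against a vectorized encoding of the other,
reporting per-motif fractions at or above the cutoff (≥, since the
printed fractions' convention is unstated) and the exact pair count.

## Repertoire, pathogens, associations

Repertoire analysis keeps allele–peptide pairs with affinity < 50 nM AND
rank < 0.5% AND specific T cells in at least two carriers; individuals
need at least 20 *recognized* presented peptides (the inclusion sentence
refers to peptides for which specific T cells were found). Fractions of
recognized peptides per TCEM-attribute group are compared across
individuals with two-sided paired signed-rank tests.

Pathogen np fractions are window-weighted by default (prevalence in the
proteome; a distinct-motif mode exists). Motifs never seen in the human
proteome are np by the frequency criterion. Per-allele presented fractions
use strong binding (50 nM / 0.5%); an allele with zero predicted binders
falls back to its N lowest-affinity peptides, N being the median bound
count of the other same-locus alleles (error if undefined). Association
studies are pooled by within-study rank percentiles of odds ratios (average
ranks on ties), restricted to allele groups present in at least 75% of
studies; the lowest mean percentile is labelled protective, the highest
risk. Serotype groups average all member alleles, two-digit allele groups
only members classified as common.

Statistical conventions: all tests two-sided, no multiple-testing
correction in the headline analyses (a Benjamini–Hochberg helper exists);
hydrophobicity is the Kyte–Doolittle mean over the five motif residues
(scale pluggable, since none is standardized for this use); multivariate
logistic models encode the attributes as categorical groups by default with
a raw-value mode.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed) and emit ground truth
alongside their outputs. Defaults (`SimulationConfig`): 120 proteins of
Poisson-mean length 400; residues i.i.d. from a skewed composition in which
the six residues most common in human proteins carry 90% of the mass. The
skew is what makes desk-scale proteomes reproduce the *long-tailed* TCEM
frequency distribution of the real proteome (≈3–4 windows per observed
motif): under a uniform 20-letter alphabet every motif would be a singleton
and the nonrare class empty. Expression counts are negative-binomial
(dispersion 0.2) over lognormal gene means with 5% housekeeping genes at
10-fold expression. Cleavage tables multiply the position −1 prevalence of
hydrophobic residues (Kyte–Doolittle > 0) by θ = 0.2 and add lognormal
positional jitter of scale 0.15·(1−θ); the jitter is required for the
planted deficit to be observable at all — a single deviating flank position
among ten identical ones is absorbed exactly by the site median — and real
digestion profiles deviate at every position; θ = 1 reproduces the uniform
table exactly. Immunogenicity is logistic in the three attributes
(β₀ = −0.5, β_freq = 1.0, β_cleav = 0.8, plus a quadratic expression bump of
height 1.5 peaked at the middle percentile). TCR scans decay as
exp(λ·(sim−1)) with λ = 6, which places the analytic 10%-binding cutoff
1 + ln(0.1)/λ ≈ 0.616 inside the observed single-substitution similarity
range. Repertoires default to 296 peptides and 27 individuals (22 enter the
planted-penalty power analyses), base recognition rate 0.15, np penalty
0.5. Synthetic pathogens are built from single-window (9-residue) proteins
so each window's np status is exactly controllable; a contiguous proteome
would create uncontrolled overlapping windows. Association tables plant 6
risk and 7 protective allele groups with presented-np fractions centered at
0.7 and 0.3.

Deliberately **not** emulated: real HLA binding motifs (the toy predictor
anchors only positions 2 and 9), homology and domain structure within
proteomes, codon or isoform structure, the true human amino-acid
composition, and assay-level noise heterogeneity. Passing tests therefore
demonstrate that the pipeline recovers planted effects of realistic shape
and direction at desk scale — not that the real-data effect sizes would be
reproduced.

## Problem sizes

The test suite and the acceptance script run on one CPU in a few minutes:
proteomes of ≈47,000 windows (oracle-equivalence checks up to 10^5
residues), assay datasets of 2,000 peptides × 100 replicates for the
frequency-effect recovery, 30 replicates for the lowess peak location, 25
repertoire replicates at 22 individuals, and one full 43 × 323,470
cross-reactivity scan (13,909,210 pairs, streamed). These sizes were chosen
as the smallest at which the planted effects are comfortably detectable.

## Known limitations

- The geometric-mean similarity normalization is an interpretation of an
  under-specified upstream convention; the pluggable normalization exists
  precisely because a different denominator would shift cutoffs.
- The k-tuple de-duplication reimplements the distance, not the original
  aligner's exact parameters; ties in the exclusion rule are resolved by a
  documented deterministic convention the original method leaves open.
- Terminal-site and terminal-window handling in the cleavage cascade are
  under-specified upstream; both behaviors are implemented and switchable,
  and defaults are the least destructive readings.
- Expression cutoffs for "low/high" groups are tertile boundaries by
  assumption; no printed cutoff exists to verify against.
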