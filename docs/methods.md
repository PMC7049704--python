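# Methods

## Scope and model

`leakyscan` implements a genome-wide analysis of start-codon selection in
compact fungal genomes: annotating transcript ends from 5'/3'-end sequencing,
modelling the Kozak context of start codons, enumerating upstream and
downstream AUGs, quantifying translation with ribosome footprints, and
testing how uAUGs shape translation efficiency and NMD sensitivity. Because
the analyses are only meaningful against known answers, the package ships a
synthetic-data generator whose ground truth drives recovery tests at every
stage.

### Transcript-end annotation

Per-position 5'-end counts are filtered to positions present in **all**
replicates of a condition, scaled by spike-in size factors (reference spike
total / sample spike total), and chained into clusters wherever consecutive
positions are at most 50 nt apart (a gap of exactly 50 joins; the boundary
is read as inclusive). TSS clusters are then tested against a no-decap
control library with the decap ratio

    R = (w_i / Σ w) / (w_i^nodecap / Σ w^nodecap),

keeping clusters with R > 1 (strict). Both denominators are genome-wide
totals, matching the double-sum notation of the ratio. Clusters are matched
to control clusters by span overlap on the same strand, summing multiple
overlaps; clusters with no control overlap are kept (R = ∞) — absence from
the control is no evidence of artifact, and the rule avoids division by
zero. Clusters are assigned to a gene when their peak lies in the annotated
leader or within 1000 nt upstream of the CDS start (3'-side mirrored for
polyA clusters), ties to the nearest CDS edge. Clusters carrying at least
10% of their gene's normalized signal in at least one condition are
prominent; the most distal prominent cluster's **peak** (weight mode, not a
span edge) becomes the transcript end. Genes without clusters keep their
previous annotation; changes over 100 bp are applied but listed for manual
curation; a proposed end inside the CDS flags the gene and is not applied.
CDS coordinates are never altered. Coordinates are 0-based half-open
internally and 1-based inclusive only in GFF3.

### Read-level filters

TSS-seq reads must contain the library's 5' tag — parsed literally as 11
arbitrary nt, the literal CGCCGCG, then 3 arbitrary nt — and the 3' adapter
(full match anywhere, or a ≥10-nt adapter prefix at the read end); both are
removed, no mismatches tolerated, and reads lacking either are rejected
(rejection is a value, not an exception). PolyA-site reads are trimmed of a
maximal terminal A-run of ≥5 (exact A only) and kept only if they align
after trimming but **not** before: a read genomic before trimming copied a
templated A stretch (internal priming) rather than a polyA tail. Alignment
for synthetic genomes is exact substring search on both strands; unique /
ambiguous / unmapped are distinguished, and minus-strand hits report the
forward-strand interval.

### Kozak model

The position frequency matrix spans −12..+14 around the A of the AUG, built
from AUG-aligned contexts of the most highly translated genes (top 5% by
footprint TPM, or the top 400 where a genome has more than 8000 genes), with
a Laplace pseudocount of 1 per base per column; N bases (transcript-edge
padding) are excluded from counts. The score of a context over a window
(wide −10..−1, narrow −4..−1) is

    score = Σ_pos f(pos, base) / Σ_pos max_b f(pos, b),

a [0,1] similarity with score(consensus) = 1; N positions contribute the
column mean to numerator and denominator alike, making edge padding
uninformative rather than penalizing. The downstream context (+4 onward) is
recorded but never scored — it is confounded with N-terminal amino-acid and
codon-usage signal and carries little sequence bias. A log-odds alternative
(`kozak_score_logodds`) is exposed for sensitivity analysis since the exact
historical normalization of published score values is not uniquely
determined by their printed range; the sum-ratio form is the package
default. Information content per position is `2 + Σ_b f log2 f` bits;
logo heights are `f × IC`, exported as TSV (renderable with matplotlib —
no dedicated logo library is required).

### Start-codon enumeration

A leader ATG is a uAUG iff its distance to the annotated start is not a
multiple of 3, **or** it is in frame with an intervening stop codon; in-frame
stop-free ATGs are N-terminal extensions and are excluded. Out-of-frame
uORFs without a leader stop extend into the CDS and are retained, with their
stop position recorded. Distances are measured from the TSS to the A of the
codon in spliced transcript coordinates, and the proximity rule classifies a
gene as '1+ far' when any uAUG lies more than 20 nt from the TSS, '1+ close'
when all are within 20 nt. Near-cognate scanning covers the nine
single-substitution neighbours of ATG, reported when their wide score
(computed over the same upstream window; the anchor is outside it) passes a
threshold (default 0.9); the scan is off by default because near-cognate
starts are a case-by-case phenomenon. Dual-localization candidates are genes
in the top half by RNA abundance whose first downstream AUG outscores the
annotated one by more than 0.1 (wide window), labelled in/out-of-frame and,
when an external mitochondrial-targeting-prediction table is supplied,
MTS±.

### Translation quantification and the leak fit

TPM is the length-normalized rate scaled to 10^6 per sample; TE is footprint
TPM / RNA TPM for genes with RNA TPM ≥ 1 (a floor against ratio
instability). Footprint 5' ends are assigned to A-sites at a fixed +15 nt
offset by default, overridable per read length. Occupancy around a candidate
start is the density over the 10 codons **after** the start codon (the codon
itself is excluded; windows are clipped at the transcript end), with a
pseudocount of 0.5 reads per window before ratios. The uAUG-vs-aAUG contrast
uses single-uAUG genes in the top half by RNA abundance; the footprint
log2 ratio is regressed on the score difference by least squares (slope,
R², two-sided t-test), with the RNA log2 ratio as the score-free negative
control. The logistic initiation model is fitted by nonlinear least squares
of `log2[p(s_u) / ((1−p(s_u)) p(s_a))]` against the observed log2 window
ratios, estimating (slope, midpoint) directly — no free intercept, because
under the scanning recursion the window-density ratio equals the flux ratio
exactly in expectation.

### Group statistics

Counts are normalized by median-of-ratios size factors (median over genes
nonzero in every sample of count / geometric mean across samples), rescaled
to geometric mean 1 so normalization is idempotent. Wild-type vs
NMD-deficient fold change is `log2((mut+1)/(wt+1))` on normalized means.
Group contrasts (uAUG count 0/1/2+, proximity classes, and — among
single-uAUG genes — Kozak-score bins split at 0.8 or at quantile edges) use
the one-sided two-sample Kolmogorov–Smirnov test: D⁺ = sup(F_x − F_y) with
the asymptotic tail p = exp(−2mnD²/(m+n)), switching to the exact
distribution when both samples have ≤25 observations. The asymptotic p is a
tail approximation and the exact p is discrete, so calibration is asserted
where decisions are made: the measured rejection rate at nominal α = 0.01
is 0.006–0.009 across seeds (and ~0.05 at α = 0.05), verified against a
permutation oracle. P-values are reported raw; only a handful of planned
adjacent contrasts are run, so no multiplicity correction is applied.
Negative-binomial differential-expression machinery is deliberately not
reimplemented; the supported inference is the group-level fold-change
comparison above.

## The synthetic-data generator

`SimConfig` defines the study conditions; all randomness flows from one seed
(per-operation child streams), and identical (config, seed) give
byte-identical outputs.

**Gene anatomy.** Single-exon genes (an optional flag can insert one leader
intron for annotation-update testing; splicing is otherwise outside the
analytical core) with lognormal lengths: leader median 105 nt (σ=1.0),
3'UTR median 127 nt (σ=0.85), CDS median 470 codons (σ=0.45) — leader/3'UTR
medians match the organism the analysis targets, and σ values reproduce the
observed mean/median ratios. Genes are placed on both strands with ≥100-nt
spacers.

**Leaders and planted uAUGs.** uAUG counts are Poisson with 0.0086 expected
uAUGs per leader nt (≈10000 uAUGs per 6-7k-gene genome given the length
distribution). Each planted uORF is a 48-nt block — 12-nt context, ATG, ten
sense codons, TAA — whose context is hill-climbed to a target wide score
drawn uniformly from [0.30, 0.98], so planted scores span the whole logistic
transition rather than only the high range that straight matrix sampling
produces. Micro-padding between blocks sets each uAUG out of frame (2/3 of
plants) or in frame with its own intervening stop (1/3). Every other ATG in
the leader is destroyed (T→C, which can create neither an ATG nor a stop),
so the planted set **is** the complete uAUG set, verified by an internal
scan at generation time. The ten-codon uORF length means the downstream
occupancy window measures pure uORF translation. The annotated-AUG context
is sampled from the truth matrix directly (realistically high-scoring);
downstream AUGs arise naturally from random sense codons.

**Truth matrix.** A Cryptococcus-like frequency matrix: A-rich −4..−1 with C
enrichment at −1/−2/−5, a weak C bias out to −10, an essentially invariant
AUG and an uninformative downstream side.

**Leak model.** Initiation probability p(s) = 1/(1+exp(−slope·(s−mid))) with
slope 8 and midpoint 0.6. No quantitative leakiness-vs-score calibration
exists to copy, so these are free parameters chosen so that typical
annotated-start scores (~0.83) initiate with p≈0.86 while mid-range uAUG
scores leak appreciably — strong starts nearly deterministic, weak ones
porous. Scanning is strictly sequential and reinitiation is not modelled
(the leak-only reading of uORF action); the flux reaching each AUG is the
product of (1−p) over all upstream AUGs, and the first downstream AUG
receives what leaks past the annotated start.

**End-seq libraries.** True TSS reads (50/gene/replicate, scaled by a
per-sample depth factor that also sets the spike-in count) scatter around
the planted TSS with σ = 3 nt, truncated at 3σ so every true-library
position stays within the recovery tolerance. False clusters (degradation
5' ends) appear at 0.5 per gene, placed in gene-upstream windows but ≥80 nt
from the true TSS — closer plants would chain into the true cluster under
the 50-nt rule and the label would name nothing distinct, which is also why
co-located degradation products are undetectable by construction (a real
limitation of the filter, not of the simulation). Each false cluster enters
each replicate with probability 0.7 (so ~1/3 survive the all-replicates
consensus) and is enriched 3× in the no-decap control, which captures true
capped ends at only 10% — the control is dominated by non-capped species,
as its chemistry intends. PolyA-site reads carry non-templated 8–14-nt A
tails; a configurable fraction (default 0.1) instead end inside an 8-A
genomic stretch planted in the 3'UTR, making them exact genomic substrings —
the internal-priming signature.

**Expression.** RNA abundances are lognormal (σ=1). Count tables are Poisson
around abundance × length (× initiation flux for footprints; × the gene's
NMD fold change for the upf1-null RNA sample), with optional gamma-Poisson
overdispersion (off by default, matching the package's group-level rather
than per-gene inference). The NMD fold change is 1 + 2 × (total uORF
initiation flux): stabilisation grows with how many scanning complexes
terminate at uORF stops, which makes it monotone in uAUG count and score.
Per-position footprints place 1 read/codon at flux 1 on abundance-average
genes (deep riboprofiling territory; shallower settings leave log-ratio fits
pseudocount-dominated), with 5'-ends offset −15 from the A-site and frame
jitter drawn from the configured frame weights (0.77/0.10/0.13, the
composition observed on well-expressed fungal ORFs); read lengths peak at
28 nt. RNA coverage is uniform.

**What the generator does not emulate.** Sequencing errors, introns in CDS,
reinitiation and near-cognate initiation (the latter available behind a
flag), isoform heterogeneity, condition-dependent transcription-start
shifts, cycloheximide artefacts beyond the windowed-ratio design, and
co-located degradation products (above). Passing recovery tests therefore
demonstrates the correctness of the pipeline's logic under the scanning
model's assumptions, not robustness to every artefact of real libraries.

## Verification sizes and numerical choices

The full-scale recovery checks run on 2000-gene studies (cluster
precision/recall ≥0.95, decap removal ≥90% at retention ≥95%, exact
uAUG/dAUG enumeration, leak parameters within 20%, frame fractions within
binomial error, KS type-I within [0.003, 0.03] over 2000 null draws);
unit-level fixtures use 60–800 genes. Matrix estimation error at 500
contexts is asserted on the mean and 95th percentile (< 0.02 / < 0.05) with
a 0.1 uniform bound — per-cell multinomial noise at n=500 makes a uniform
0.05 bound unachievable for any correct estimator (σ≈0.021 over 108 cells).
Ties in hiTrans selection and cluster peaks break deterministically
(lexicographic gene id; 5'-most position). Degenerate inputs error loudly:
empty context sets, zero spike totals, all-zero count vectors, constant
score differences, sub-3-gene regressions.
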