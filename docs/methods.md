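# Methods

This note documents the models, conventions and design choices behind
`tribescope`, in the order data flows through the pipeline.

## Editing-event calling

Pileups are taken by linear scan over a SAM file (unmapped, secondary,
supplementary and duplicate-flagged reads skipped; MAPQ ≥ 1 by default).
Point positions are 1-based throughout (SAM/VCF convention); interval
geometry is 0-based half-open (BED convention), converted at the BED
boundary.

A mismatch call at a column requires at least `min_alt_reads = 2`
observations of one alternative base, each at Phred ≥ `min_phred = 31`.
The phrase "quality above 30" is implemented as strictly greater, i.e. ≥ 31.
The depth filter counts only quality-passing supporting reads — the stricter
of the two possible readings (the alternative would count all supporting
reads and require the quality only somewhere), chosen because it is
reproducible from the column alone and monotone in both thresholds. N bases
and deletions are ignored; two alternative bases passing at one site yield
two calls; calling is strictly per sample.

Calls at known SNP or known-editing positions are removed by exact
(contig, position) membership before the strand-aware reduction: A>G calls
inside plus-strand 3′UTRs and T>C calls inside minus-strand 3′UTRs become
editing events, annotated per overlapping gene (a position covered by
features of both strands produces one event per matching feature).

## Target ranking

Editing events are summed per gene over its annotated 3′UTRs; genes whose
transcripts all carry decay/pseudogene biotypes (nonsense-mediated decay,
non-stop decay, processed transcript, retained intron, unprocessed
pseudogene) are excluded; replicate samples of a condition are summed before
regression. Counts enter the OLS untransformed (a `log1p` option exists, off
by default); genes with zero events in both conditions are retained because
they anchor the fit near the origin.

"Standardized residual" is read as the internally studentized residual
rᵢ/(s√(1−hᵢ)) — the conventional regression-diagnostic meaning; the raw
residual is available via a flag. Ranking is by residual descending with
deterministic ties broken by gene id ascending. When the universe is smaller
than the requested top/bottom sizes, both shrink to half the universe with a
warning, keeping the sets disjoint. A background condition with zero
variance across genes leaves the regression undefined; the error message
points at ranking by the test-condition counts directly.

## Set statistics

The binomial overlap convention is stated in every result object: p is the
upper tail of Binomial(n = |A|, p = |B|/universe) at k = |A∩B|, expected
overlap |A||B|/universe, fold enrichment k/expected. The universe defaults to
the expression-filtered gene count of the analysis at hand and is always
user-overridable and logged, since cross-study universes differ. Gene ids are
matched after case-folding and version-suffix stripping (`GENE.3` → `GENE`),
both configurable, because external lists come in different id dialects.

## Derepression

### TMM normalization

The trimmed mean of M-values is computed against a reference sample (the one
whose upper-quartile count fraction is closest to the sample mean). M-values
here are log2 ratios of **raw** counts against the reference, so the
resulting factor absorbs sequencing-depth differences together with
composition bias and the normalized count is simply `count / factor`
(factors rescaled to geometric mean 1). This differs from implementations
that compute M on library-size-relative counts and return a composition-only
factor; the single-factor convention keeps the downstream "< 50 normalized
counts in any sample" filter interpretable on one scale. Trimming removes
30% of extreme M-values and 5% of extreme A-values from each tail, and the
surviving M-values are averaged with inverse asymptotic-variance weights
(N−y)/(Ny) summed over both samples. Genes with zero counts in all samples
are removed before normalization (undefined in M/A space); a uniform
depth-only shift (every M equal) is returned exactly without trimming.

### DTS two-sample test

The statistic is a variance-reweighted integral of the distance between the
two empirical CDFs: over consecutive distinct pooled order statistics
t₍ᵢ₎ < t₍ᵢ₊₁₎,

  D = Σ |E_x(t₍ᵢ₎) − E_y(t₍ᵢ₎)| · (t₍ᵢ₊₁₎ − t₍ᵢ₎) / √(H(t₍ᵢ₎)(1 − H(t₍ᵢ₎)))

with H the pooled ECDF; boundary intervals where H ∈ {0, 1} contribute
nothing (this handles the weight singularity). Ties, including ties across
groups, are handled by aggregating to distinct pooled values before
integration. D is invariant to adding a constant to both samples and scales
linearly with a common positive factor.

Significance comes from label permutation: when C(n_x+n_y, n_x) ≤ `n_perm`
all label assignments are enumerated and p is the exact fraction with a
statistic at least the observed one; otherwise `n_perm` seeded random
permutations are drawn and the add-one estimator (1 + hits)/(1 + n_perm) is
reported so Monte-Carlo p is never 0. Under the exact path the 3-vs-3
separation {1,2,3} vs {4,5,6} gives p = 2/20 = 0.1 (the observed split and
its mirror). Permutations are evaluated vectorised in chunks, so the
600-vs-14,000 comparison at 2,000 permutations runs in seconds.

Published descriptions of this comparison sometimes label the test
"Wasserstein distance" while defining the reweighted-ECDF statistic above;
the reweighted definition is implemented, and the naming discrepancy is
noted rather than resolved.

## Positional analysis

Eligible 3′UTRs are monoexonic, the longest isoform per gene (ties by
transcript id ascending), at least 40 bp long, and contain exactly one
external binding site. Distances are sequence distances in UTR-local
coordinates (for monoexonic UTRs the projection is an offset). Every editing
event in an eligible UTR contributes a distance by default; a nearest-only
flag exists because published procedure descriptions leave this open. The
background draws one integer dummy position uniform on [1, L] per UTR per
iteration (default n = 100); the continuous-uniform option is off by
default. For a site at local position s the large-n mean background distance
is (s² + (L−s)²)/(2L), which the tests verify at 10,000 draws.

## Single cells

Normalized linker level is (raw linker reads + 1)/total reads; the
pseudocount keeps log10 finite. A read counts as a linker read if any offset
alignment of the shorter sequence within the longer, in either orientation,
has at most one Hamming mismatch. QC (defaults at full scale): drop cells
with < 9,000 detected genes or < 150,000 deduplicated reads, then drop cells
that are **both** below the log10-normalized-linker floor (−4.5) **and**
below 1,000 editing events — a cell failing only one of the two is kept. The
K562-style mode instead calls a cell transfected from a single raw linker
read. Whether linker normalization divides by total raw or total mapped
reads is ambiguous in published protocol descriptions; total reads from the
metadata table is used here. Published analyses also applied an additional,
undescribed cell exclusion after these filters; it is not emulated.

Module scores are computed on counts-per-million expression (scale 10⁶):
score = mean(marker genes) − mean(control draws), where each marker gene
contributes `n_ctrl = 100` controls sampled from its average-expression bin
(24 rank bins; without replacement when the bin allows, with replacement
otherwise) and the control mean is taken over the draws with multiplicity.
Weighting controls per member gene keeps the control mean expression-matched
to the marker mean even when several markers share a bin, which centres null
scores at/below zero; a set-union control mean under-weights repeated
high-expression bins and can bias scores positive. A test cross-checks the
scores against the field-standard `scanpy.tl.score_genes` (r > 0.95).

Phase assignment defaults to the conventional rule: the phase of the larger
of the S and G2M scores when positive, else G1. The published variant that
forces cells with *both* scores above 50 into G1 is implemented behind a
flag (`both-high-g1`) and logged when used, because it contradicts common
practice. The published early/late split within phases was drawn by eye from
an embedding and is not reproducible; here each phase is split into equal
halves by rank of its defining score (G1 ranks by S-score as progression
toward S), the extra cell of an odd count going to `early` — deterministic
and documented.

Spike-in pseudobulk normalization divides pooled per-substage values by
factor_s = (spike-in reads of substage s)/(cells in substage s). Spike-in
reads are identified by the `ERCC-` contig-name prefix. Differential
targeting across stages builds, per gene, a stage × {edited, depth-proxy
remainder} contingency table from normalized event counts and tests it by
chi-square (Fisher's exact for two-stage tables with small expected counts;
no exact r×c test is available), with Benjamini–Hochberg adjustment across
genes. No published recipe exists for this contrast; outputs carry an
explicit artifact-defined marker.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
sequencing realism. One contig per gene carries a single-interval 3′UTR with
at least 10 transcript-strand adenosines (forced if the random sequence
falls short). A configured fraction of UTR adenosines (default 0.2) becomes
a planted editing site; per-read editing probability at planted sites is
0.5 in target genes under the fusion condition and 0.05 elsewhere and in the
deaminase-only condition; the control condition carries no editing. The true
per-adenosine rate induced in cells is unknown, so these defaults were
chosen once for statistical power at toy depth (~30 reads/gene, 75 bp
reads). Heterozygous SNPs (density 0.002/bp, allele fraction 0.5) and
uniform sequencing errors (0.001/base) are planted as confounders; SNPs are
never placed on planted editing sites so the truth manifest stays exact — a
real pipeline does face that collision, and its dbSNP exclusion then costs
sensitivity. Base qualities are two-valued (20/37, 10% low) so the Phred
filter has a crisp boundary. Alignments are emitted ungapped: gaps are an
upstream-aligner concern not exercised by any filter here.

Expression tables are negative binomial (dispersion 0.05, lognormal
baseline means) with library sizes varied up to three-fold; target genes are
multiplied by 2^0.18 in the miRNA-inhibited scenario. Single cells are
scaled ~100× below real plate-based depth (QC thresholds in tests scale
accordingly); cells are allocated to G1/S/G2M in exactly equal proportions —
a deliberate simplification of an asynchronous population that makes the
spike-in "flatness for constant genes" property exact under the
pooled-value/factor normalization formula, which otherwise retains a
cell-number term. Transfected cells (exact configured fraction) receive
Poisson linker reads and elevated editing; marker genes (30 per phase,
4-fold up in their phase) drive the cell-cycle scores; every cell receives
Poisson spike-in reads. Linker reads exist both as raw sequences and aligned
to a dedicated `linker` contig so the scan-based and alignment-based
counting paths can be checked against each other.

All randomness flows from the config seed through named substreams (stable
hashes of stage names), so identical configs are byte-identical across runs
and adding a stage never perturbs another stage's draws.

### What passing tests do and do not show

The generator has no splicing, isoform complexity, UMIs, fragment-length
structure, mapping ambiguity, strand-specific library artifacts or doublets.
Recovery results (planted targets found, phases assigned, derepression
medians recovered) therefore validate the statistical machinery and its
thresholds, not robustness to alignment artifacts or annotation errors in
real data. In particular the clean separation of planted targets at the
default rates should be read as an internal-consistency check, and the TMM
filter interplay is only exercised at modest composition bias.

## Problem sizes

The test suite and the acceptance script run the headline analyses at the
scales the analyses were designed around: 1,000 genes / 50 planted targets
for the alignment→calling→ranking recovery; 600 targets among 14,600 genes
for derepression; 1,000 null repetitions at 199 permutations for DTS
calibration; 10,000 draws for the positional closed form; 300 cells for
phase recovery. These sizes give sub-minute runs on one CPU while keeping
every statistical check well-powered.

## Known limitations

- Per-site editing proportions are not modelled (no beta-binomial layer);
  the ranking operates on event counts, as specified.
- Joint calling across samples, indels and hyper-editing clusters are out of
  scope.
- The GTF reader handles `three_prime_utr` features with standard
  gene_id/transcript_id attributes; exotic attribute dialects are not
  supported.
- The binomial enrichment universe is a user responsibility; the default
  (filtered annotation size) is logged but no attempt is made to harmonise
  universes across external lists.
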