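# Methods

## Coordinate conventions and interval algebra

All coordinates are 0-based, half-open (BED). Merging follows `bedtools
merge -d g`: after sorting, two intervals on one chromosome join iff
`next.start − prev.end ≤ g` (so a separation of exactly *g* merges, *g* + 1
does not; abutting half-open intervals always merge). The implementation is
verified against a per-base dilation oracle and against the bedtools binary
itself in the test suite. Overlap counting requires each set to be
internally non-overlapping and counts an interval as shared when it overlaps
any interval of the other set by at least `min_overlap_bp` (default 1).

Nearest-TSS linking measures distance 0 when the TSS lies inside the region
and otherwise base pairs to the nearest contained base; a link is made only
within 10 kb (configurable), and distance ties break toward the
lexicographically smaller gene id. Feature annotation labels a region by its
midpoint with precedence promoter > 5'UTR > 3'UTR > exon > intron > TTS >
intergenic. Promoter windows are 2,000 bp upstream / 500 bp downstream of
the TSS (strand-aware) and the TTS window is ±500 bp of the transcript end;
annotation pipelines differ on these, so both are parameters. Intron
intervals absent from an annotation are inferred as gene body minus declared
blocks.

## Signal model and threshold calibration

Per-region, per-stage accessibility is
log₂(mean 25-bp-bin signal × 10⁶ / library total + 1): a counts-per-million
scaling with pseudocount 1 chosen so that jointly rescaling track and
library leaves values unchanged, and so that values are nonnegative. The
log base is configurable (2 by default; 10 supported for figure-style
output).

The open/closed cutoff is calibrated, not fixed: background intervals are
sampled length-matched (with replacement from atlas lengths) and placed
uniformly over chromosomes weighted by size, rejecting any overlap with the
atlas (bounded retries; coordinate sampling rather than value permutation).
The threshold is the empirical (1 − FPR) quantile (linear interpolation) of
the background signal, FPR = 0.01 by default, so the fraction of background
strictly above it cannot exceed the target. At least 100 background values
are required; fewer makes the tail quantile unstable and is an error. A
fixed threshold can be supplied to reproduce an analysis whose cutoff was
reported as a number (such cutoffs are library-specific and do not
transfer). Calls are strict: a value exactly at the threshold is closed.

When the pipeline runs from files, the background regions are quantified on
every (condition, stage) track and the values pooled into one global
threshold — one cutoff for the whole course, matching the single-threshold
design of the analysis this package operationalises.

## Trajectory classes

With ordered stages s₁…sₙ (n ≥ 3) and boolean open calls:
PO = open everywhere; NEVER = closed everywhere; CO = exactly one
closed→open transition and no open→closed (hence first stage closed, last
open), with the switch stage defined as the first open stage; OC the
converse; everything else TRANSIENT ("once altered, remained consistently"
is the defining property of CO/OC — any reversion is transient). Per-stage
CO/OC counts are cumulative in the switch stage, which is the reading
consistent with counts that increase monotonically over the course; PO
counts are flat. The classifier is tested against an independent
shape-matching oracle on every pattern up to 2⁸.

The switch-stage co-occurrence matrix between conditions is restricted to
regions carrying the same class (CO, or OC) in both conditions; its total
therefore equals the shared-class count, minus any region lacking a switch
stage (counted and reported, never silently dropped).

## Fuzzy clustering and cluster categories

Transient regions are clustered on per-region z-standardised trajectories,
computed per condition and concatenated, following the standardisation
convention of the Mfuzz soft-clustering package. Clustering is Bezdek fuzzy
c-means (Euclidean distance), c = 10 and m = 2.0 by default, seeded random
membership initialisation, alternating updates to a 10⁻⁶ membership-change
tolerance or 500 iterations. Memberships are row-stochastic by
construction; points coincident with a centre get full membership there;
c = 1 returns all-ones. scikit-fuzzy is not a dependency — the algorithm is
~30 lines and owning it keeps the package's clustering deterministic and
seedable; hard k-means from scikit-learn serves as an independent
cross-check in the tests.

Cluster mean shapes are categorised per condition: "up" if the final z ≥
+0.5 with Spearman(shape, stage index) ≥ 0.6; "loss" mirrored; "transient"
if an interior extremum clears both endpoints by ≥ 0.5 z (peaks and dips
both count — transiently-closed shapes are dips); "flat" if the z span is
< 0.5. Both conditions agreeing gives a shared category; one labelled with
the other flat gives a condition-specific category; every other combination
is unclassified. These cutoffs operationalise what is, in the source
analyses, a manual figure-based grouping; all four are parameters. Note
that condition-specific "loss" is not a recognised category and maps to
unclassified.

## Expression statistics

Expression is a gene × replicate FPKM table with a replicate → (condition,
stage) map. Class-wise statistics pool linked genes' per-gene stage-mean
FPKM and compare each stage against the same genes' baseline (hiF-T) means
with a two-sided Mann–Whitney U (exact null for pooled n ≤ 20 without ties,
tie-corrected normal approximation otherwise).

Upregulation requires, at every post-baseline stage: stage mean > 5 × the
baseline mean, Welch-t p < 10⁻⁴ on log₂(FPKM + 1) across replicates, and
stage mean FPKM > 5. The test behind the p criterion is not prescribed by
the criterion's source; Welch on log-transformed values is the conventional
choice and is configurable. With fewer than two replicates at any stage the
p criterion is skipped with a prominent warning. With exactly two
replicates the Welch degrees of freedom can collapse toward 1, making
p < 10⁻⁴ unreachable regardless of effect size — a genuine property of the
criterion, not of this implementation — so the synthetic default is three
replicates per (condition, stage), the level the corresponding RNA-seq
protocols aim for.

Differential expression between two replicate groups is Welch-t on
log₂(FPKM+1) with Benjamini–Hochberg correction across all tested genes
(via statsmodels); DE iff fold > 2 (in either direction) and q < 0.05.
Zero-variance equal-mean degenerate genes get p = 1. On simulated global
nulls the mean rejection fraction stays below the nominal level (checked
over 200 × 1,000 genes).

## Candidate funnel and pattern groups

Candidates are a pure intersection: genes whose TSS lies within 10 kb of
any input region (gained-accessibility regions plus an optionally selected
transient cluster, a config key), ∩ upregulated, ∩ the user-supplied
epigenetic-factor list (no list is bundled). Evidence per candidate records
the nearest region, its distance and its switch stage. Funnel counts are
monotone non-increasing by construction.

Pattern groups per candidate, from per-stage mean FPKM: late-surge (group
3: last-two-stage mean ≥ 2 × the earlier maximum while earlier stages stay
below 5 FPKM) is tested before progressive-up (group 1: tie-corrected
Spearman ≥ 0.7 and final ≥ 2 × baseline), because a late step function also
produces Spearman ≈ 0.8 and would otherwise be swallowed by the monotone
rule; then low-stable (group 4: all means < 5 FPKM, fold span < 2); else
group 2 (expressed, no strong trend). All cutoffs are parameters; the
grouping operationalises a descriptive classification.

## Binding targets and correlation signs

Sites are called with the same calibrated-threshold machinery as open
chromatin (strictly above). Target genes have a TSS within 10 kb of any
site — 10 kb adopted for symmetry with the ATAC annotation rule, since
"closely located" is otherwise unquantified — and overall mean FPKM ≥ 1.
Per target, r = Pearson correlation (Spearman available) between the per-
stage mean log₂(FPKM+1) profiles of target and isoform over one condition's
stages; sign is the sign of r; exactly-zero or undefined correlations are
excluded from the positive fraction with a warning and a logged count.
Nomination intersects a sign-filtered target set with a GMT gene-set entry;
the (isoform, sign, gene set) triples are configuration.

## Synthetic study: what it emulates, and what it does not

The generator plants, per condition: region trajectories (PO/CO/OC/NEVER/
TRANSIENT at configured counts; CO/OC switch stages uniform over admissible
stages; TRANSIENT as open-closed-open or closed-open-closed with two
switches), per-stage log₂ signals from open/closed Gaussians (means 6.0 /
2.0, sd 0.7 — clean separation around a calibrated cutoff near 3.6, i.e. a
4.2-like regime; draws truncated at 0 since log-CPM values are
nonnegative), and a pseudo-input sample from the closed distribution. The
same class is planted in both conditions with independently drawn switch
stages — so switch-time co-occurrence has exact planted marginals, while
cluster categories on default data come out mostly unclassified (there is
no planted cross-condition shape structure; the categoriser is validated on
planted centre shapes instead).

Expression couples linked genes to their region: stage mean log₂ FPKM =
gene baseline (N(3,1)) + coupling × z(region signal across stages), with
N(0, 0.5) replicate noise; forced-upregulated plants (the funnel's true
positives) jump from FPKM 2 to 100 after baseline with sd 0.01 replicate
noise. Binding plants two isoform genes with opposite monotone expression
ramps (amplitude 2 on log₂), target genes whose profiles are lines of the
planted slope sign plus N(0, 0.1) stage noise (|r| ≈ 0.98), a configured
count of shared sites placed near dedicated shared target genes, and a
configured fraction of low-expression targets (FPKM 0.3) to exercise the
filter. Geometry is deliberately simple: evenly spaced 500-bp regions on
one chromosome, one gene 300 bp upstream of each linked region, binding
genes 30 kb apart on their own chromosome.

When written to files, tracks carry already-normalised signal (library
totals declared as 10⁶ in a sidecar), with block-constant closed-level
background (2-kb blocks) outside planted regions so that pseudo-input
placement measures a closed-like null; peak files contain the truly open
regions per stage. Everything re-parses losslessly, and a fixed seed fixes
every output byte.

What passing on this generator does **not** show: robustness to replicate-
dependent peak calling, fragment-length or GC artefacts, unequal library
depths beyond a scalar, overlapping genes, many-to-many region–gene
topology, batch effects in expression, or correlation structure between
neighbouring regions. The generator is a correctness harness for the
analysis logic, not a sequencing simulator.

## Problem sizes and numerics

Default study: 2,000 regions (400 per class), 7 stages, 2 conditions, 3
replicates, 10,000 pseudo-input values — the whole pipeline runs in a few
seconds, and the test suite scales its Monte-Carlo checks (e.g. 200 × 1,000
null genes for type-I control; 500 + 500 trajectories for clustering
recovery) to stay comfortably fast while keeping binomial tolerances tight.
Quantile interpolation is linear; fuzzy-c-means distances are clipped at
10⁻³⁰⁰ before inversion; Welch tests on identical constant groups return
p = 1; constant profiles yield undefined correlations and are excluded
rather than coerced.

## Known limitations

The atlas built from peak files cannot contain never-open regions, so
NEVER counts are zero in file-based runs (the in-memory path plants and
scores them). Funnel linking is gene-centric (a gene links to its nearest
region); a region near two TSSs contributes to both genes, and no
enhancer–promoter model is attempted. The upregulation p criterion is
power-limited at two replicates, as discussed above. Fuzzy c-means is a
local optimiser: different seeds can permute or occasionally merge
clusters; the pipeline fixes the seed from the config for reproducibility.
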