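# Methods

This package re-implements, as a tested pipeline over synthetic data with
planted ground truth, the computational analyses used to dissect how an
inducible transcription factor (Nanog, induced or withdrawn with
doxycycline in mouse ES cells) rewires co-factor binding, broad H3K27me3
domains and the LIF-dependent transcriptome.  This note records the models,
the parameters that matter, and the design choices made where the design
was genuinely open.

## Consensus binding regions (`regunet.consensus`)

Per-sample peak calls are pooled and union-merged: peaks sharing at least
1 bp merge transitively ("combined" is not otherwise specified upstream of
us; union-merge is the least-assuming reading).  Support is the number of
distinct samples contributing at least one peak to a merged region; regions
with support < 2 are dropped, as are peaks on excluded chromosomes or
overlapping a blacklist by ≥ 1 bp.  Height is the *maximum* per-bp coverage
inside the region (a peak-summit height, not a mean), scaled to reads per
million per sample and averaged over samples; the default retention
threshold is mean height ≥ 1 rpm, computed on the merged regions.  All
threshold comparisons in the package are inclusive (≥).  Summits are the
argmax of coverage averaged over samples, leftmost position on ties.

ATAC cut sites: for a fragment [s, e), the two transposition points are
s + 4 and (e − 1) − 4 (both coordinates shifted inwards by 4 bp — the
symmetric variant, exposed as a `shift` parameter for users preferring the
+4/−5 convention); the cut site and both flanking bases are incremented.
Tracks are scaled to rpm by fragment count and averaged over replicates.
Fragments shorter than 2·shift + 1 bp are rejected (the cut sites would
cross).

## Co-binding traces and clustering (`regunet.cobinding`)

Factor signal is quantified as per-bin read-start counts in a 1 kb window
centred on each region summit, rpm-normalised per replicate and averaged
within each (factor, condition).  The default bin is 10 bp: it preserves
profile shape at a 40× smaller feature space than per-bp traces and is
configurable down to 1 bp.  A region is *co-binding* when any factor in any
condition reaches 2.7 rpm at some bin (the occupancy threshold applied
directly as a parameter rather than re-deriving it from a preliminary
clustering, whose procedure is not specified); otherwise it is *solo*.

For clustering, traces are restricted to ±250 bp around the summit.  With
h⁺/h⁻ the +Dox/−Dox traces of factor i at region j, σᵢ = Σⱼₖ h⁺ᵢⱼₖ is the
factor's total +Dox occupancy, τⱼ concatenates the per-factor traces
divided by their σᵢ, and τ̄ⱼ = τⱼ / maxₖ τⱼₖ.  Dividing by σᵢ removes global
occupancy differences between factors; dividing by the per-region maximum
removes differences between regions, so k-means (Euclidean, k-means++
initialisation, n_init = 10, max_iter = 300, tol = 1e-6) groups binding
*patterns*.  The max component of every τ̄ⱼ is exactly 1, and rescaling any
factor's input globally leaves τ̄ and the assignments unchanged (bit-identical
for power-of-two factors, to machine precision otherwise).  Regions whose τ
is all-zero are excluded and reported.

k selection: the Rand index — the fraction of region pairs on which two
partitions agree, counting both together-together and apart-apart pairs
(the full index is required to compare partitions of different k without a
label matching) — is computed between assignments at k and k + 1 for k in
[2, 20], all with the same seed.  The reported recommendation is the
smallest k whose index reaches 0.9; the final choice is the analyst's.

## H3K27me3 domains (`regunet.k27`)

Broad peaks from all samples are pooled and merged transitively whenever
the inter-peak gap is ≤ 3 kb (inclusive); domains need support from ≥ 8
samples.  Reads count toward a domain when their start lies in the
half-open interval.  Replicate QC: within each condition, a replicate that
is the *strict* maximum (ties count for no sample) in ≥ 60% of domains is
excluded — exchangeable replicates sit near 1/n_rep and are never close to
the threshold.  Dynamics are clustered on condition means over retained
replicates (means, rather than totals, so unbalanced replicate loss after
QC cannot bias a condition), max-normalised per domain, k-means with k = 3.
Centroids are labelled post hoc by the mean −LIF minus +LIF difference:
most negative → `lif_loss`, most positive → `lif_gain`, remainder
`stable`.  A gene is *embedded* in a domain when its body overlaps it by
≥ 1 bp, or when the domain lies within 4 kb of the gene's TSS and overlaps
no other gene.

## Differential expression and response patterns (`regunet.de`)

The module is a documented approximation of the DESeq2 workflow:
median-of-ratios size factors (geometric-mean reference over genes with
all-positive counts); the expression filter retains genes with ≥ 10
normalised counts in *every* replicate of at least one condition; per-gene
NB2 dispersion by method of moments on normalised counts pooled over design
cells with ≥ 2 replicates, floored at 1e-8, capped at 10, with no
shrinkage; a per-gene negative-binomial log-link GLM fitted by IRLS with
log size factors as offset; Wald tests on contrast vectors; BH adjustment
within each contrast over converged genes (non-converging genes are
flagged, excluded from the FDR universe and counted in the log).  No
independent filtering and no fold-change shrinkage anywhere.

Two numerical choices depart from the nearest reference implementation and
exist because the dispersions are *unshrunk*:

* the moments dispersion is inflated by the first-order small-sample factor
  (1 + 2/df), df the summed within-group degrees of freedom;
* the Wald statistic is referred to a t distribution with the design's
  residual degrees of freedom rather than the standard normal.

Without these, plugging a 12-df dispersion estimate into the Wald
denominator is measurably anticonservative (null rejection ≈ 0.074 at
α = 0.05 on 2,000 simulated null genes, empirical FDR ≈ 0.08 at a nominal
0.05 in a 20% non-null mixture); with them the null rejection sits at
0.035–0.06 and the empirical FDR at 0.03–0.05, at no measurable cost in
power for |log2FC| = 2 effects.  With shrunk dispersions the t and normal
references coincide for any realistic sample size.

Design coding: the intercept is (+LIF, −Dox); the LIF indicator is named
`lif_withdrawn` and equals 1 when LIF is absent, so a positive coefficient
reads "up upon LIF withdrawal" and the Dox-in-−LIF effect is the sum of the
`dox` and `lif_withdrawn:dox` coefficients.  The three tested variables are
the LIF-withdrawal effect, the Dox effect in +LIF and the Dox effect in
−LIF; each gene's triple of states (up/down/ns at FDR < 0.05) is one of 27
patterns (all 27 are reported; empty ones appear with count 0).  Rescue
categories: up-on-withdrawal with Dox-down-in-−LIF is `rescued_up`,
down-on-withdrawal with Dox-up-in-−LIF is `rescued_down`, LIF-responsive
genes with no −LIF Dox response are `not_rescued_*`, anything else
`other`.  Compensation by a second guide: a −LIF target whose Dox-in-−LIF
state becomes ns or flips sign under the dual guide is `compensated`;
partial compensation is tested separately as the between-guide difference
in +Dox −LIF on the combined ~LIF + DoxGuide + LIF:DoxGuide design.

Cross-system combination uses a likelihood-ratio test of
~Cell + Dox + Cell:Dox over ~Cell (χ², df = 2, same dispersion for both
fits); the responsive union takes FDR < 0.05 in either single-system Wald
test or the LRT, with provenance flags and sign conflicts flagged rather
than dropped.  Concordance between two state assignments is the 3×3
Pearson χ² (df = 4, no continuity correction, reported as not-applicable
when a margin is zero), Cramér's V = sqrt(χ²/(N·2)), and a one-sided 2×2
Fisher test on responsive-vs-not overlap.  Heatmap z-scores use the
population standard deviation (denominator n); zero-variance rows become 0.

## Proximity enrichment (`regunet.proximity`)

Distances are measured from each tested gene's TSS to the nearest region
*summit* (matching the summit-centred convention used everywhere else), 0
when the TSS falls inside a region and +inf on region-free chromosomes.
At each of 50 log-spaced thresholds x in [1, 1e8] bp the 2×2 table
(responsive within/beyond × background within/beyond) is tested one-sided
for enrichment (hypergeometric); the universe is all expressed genes
globally, not per chromosome.  The sliding-window statistic is the fraction
of label-positive genes in each contiguous 500-gene window along a ranking.

## gRNA design (`regunet.grna`)

Candidates are every 20-nt protospacer immediately 5′ of an NGG PAM on
either strand.  Filters: GC in [35%, 85%] inclusive; no single-base run of
4 or more ("a stretch of 4 or more repeated nucleotides" read as a
homopolymer).  Off-target counting slides the protospacer over both strands
of the subject sequences, requires G at PAM positions 2–3 (N in position 1
matches anything; N elsewhere never matches), and returns a histogram over
0..4 mismatches; sites with ≥ 5 mismatches are ignored.  Ranking by
5′-end/seed mismatch composition is *not* implemented — the seed length and
ambiguity settings it depends on are unspecified — the histogram lets a
caller apply any ranking.  Cloning overhangs (5′-CACC / 5′-TTTG) are a
documentation matter only.

## Synthetic data (`regunet.simulate`)

The generators define the study conditions; every generator is a pure
function of (parameters, seed) and counts are negative binomial throughout
(Var = μ + αμ², default α = 0.05), matching the downstream model.

* **Binding**: 2,000 regions spaced 100 kb apart (the genome-wide density
  of ~28k regions over a mammalian genome) on one synthetic chromosome.
  Reads pile up as a Gaussian of sd = window/8 (125 bp for the 1 kb
  window) around each summit.  Eight amplitude archetypes (factor ×
  condition tables with high = 200 and floor = 8 expected reads per
  region, i.e. ≥ 4× the count noise sd) cover pan-factor loss, single- and
  double-factor dependence, Dox-independent binding and −Dox gains; 45% of
  regions are solo (every factor at the floor).  Six pseudo-Nanog samples
  each recall 80% of regions with ±100 bp boundary jitter, so
  support-filtering and consensus-building have real work.
* **Broad domains**: 5–30 kb domains with 8–20 kb gaps (never mergeable
  across domains at the 3 kb rule), 4 conditions × 4 replicates, class
  multipliers (stable 1/1/1/1; lif_loss 1/1/0.3/0.3; lif_gain
  0.3/0.3/1/1 over +LIF−Dox, +LIF+Dox, −LIF−Dox, −LIF+Dox), per-sample
  presence probability 0.95 and ±300 bp jitter; an optional outlier sample
  has its counts multiplied by an inflation factor (> 1 required).
* **Expression**: a 2×2 LIF × Dox design, 4 replicates per condition,
  baselines log-normal (median 200, log-sd 1), per-sample depth factors
  uniform in [0.7, 1.3], planted effect size |log2FC| = 2.  The default
  pattern mixture mirrors the proportions observed in the real system:
  52.2% silent, 18.2%/17.3% up/down on LIF withdrawal only, 4.7%/3.4%
  rescued in the two directions, and ~4% small Dox-only classes.  When
  peak linkage is requested, Dox-responsive genes are relocated so their
  TSS lies 0.3·d0–d0 from a random planted summit (d0 = 50 kb by default)
  and all other genes stay on summit-free chromosomes (hence farther than
  10·d0); because the generator must rewrite coordinates, it returns the
  relocated gene models alongside counts, samples and truth.

What the generators do *not* emulate: mappability and GC bias, fragment-
level read structure, peak-width heterogeneity, correlated dispersions,
batch effects, and spatial clustering of peaks.  Passing tests therefore
demonstrate algorithmic correctness and calibration under the assumed
model, not robustness to artefacts of real sequencing data.

## Problem sizes and reproducibility

The test-suite and acceptance-script problem sizes (2,000 binding regions,
300 domains, 2,000 genes for calibration runs, 100 QC seeds) were chosen so
every stochastic assertion has comfortable Monte-Carlo margin while a full
run stays in the tens of seconds on one core.  A single seed drives each
run; the pipeline fans it out per stage as
`stage_seed = (seed·1009 + stage_index) mod 2³¹`, so any stage can be
re-run in isolation and reproduce its outputs byte-identically.

## Known limitations

* The NB GLM refits every gene independently with a plug-in dispersion; no
  information is shared across genes, so power at n = 2–3 replicates is
  below what shrinkage-based tools achieve.
* Outlier-replicate QC assumes ≥ 2 replicates per condition and flags only
  count-inflation-type outliers (dominant maxima), not dropouts.
* The domain merger is single-linkage by gap; a long chain of peaks each
  within 3 kb of the next merges into one domain regardless of total span.
* `read_intervals` takes chromosome names verbatim; no alias resolution
  (chr1 vs 1) is attempted.
* The gRNA off-target counter is exhaustive string matching, intended for
  promoter-or-megabase-scale subjects, not whole-genome scans.
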