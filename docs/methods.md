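# Methods

This note documents the models, parameter choices and numerical decisions
behind cnvwatch, and what the synthetic-data generator does and does not
emulate.

## Coverage model and normalization

Coverage is summarised as read counts in non-overlapping 300-bp windows; a
read is counted once, in the window containing its alignment start, so window
counts are exchangeable under read placement and sum to the mapped read
total. Duplicates and secondary/supplementary alignments are excluded by
default (configurable); reads with mapping quality 0 still count — the MQ0
rule filters *windows*, not reads.

GC normalization divides each window's count by the sample's mean count over
autosomal windows with the same integer GC percentage, restricted to windows
with ≥90% accessible bases so that copy-variable or ambiguously mapped
regions do not contaminate their own normalizing constants, then multiplies
by 2 to put diploid regions at an expected value of 2. Constants are
computed **per sample**: normalization must absorb per-sample depth and
GC-bias differences, and per-sample constants make normalized coverage
invariant to rescaling any one sample's counts. The MQ0 fraction used by the
window filter is pooled across the cohort, since the filter is a single
genome-wide mask.

Window-filter thresholds (MQ0 > 2% dropped; GC bins with < 100 accessible
autosomal windows dropped) are exposed as parameters. On the small simulated
genomes used in tests and examples (10³–10⁴ windows rather than ~7.7×10⁵),
the GC-bin support threshold is lowered (typically to 30) so that the common
bins are not spuriously rare; the rule itself is unchanged.

## Copy-number HMM

States are integer copy numbers 0..K with K = 12. Emissions are Gaussian
with mean μ_k = k on the normalized-coverage scale and variance affine in
the state, σ²_k = σ²_base + k·σ²_slope, reflecting counting noise that grows
with copy number. The per-sample variance scale is estimated from autosomal
kept windows by the median absolute deviation (scaled by 1.4826), which is
robust to the minority of CNV windows; the affine profile is anchored so the
diploid state carries the estimated variance (σ²_base = s²/2,
σ²_slope = s²/4). The transition probability between any two distinct states
is t = 10⁻⁵ (self-transition 1 − K·t); with ~300-bp windows this prior makes
state changes rare but cheap enough that a genuine multi-window amplification
overrides it. All of K, t and the variance profile are configurable; the
defaults are the package's own choices.

Viterbi decoding is exact (log-space dynamic program); ties break toward the
lower copy number, a conservative choice. Amplification calls are maximal
runs of at least five kept windows with state above baseline — 2 on
autosomes and the female X, 1 on the male X. Contiguity is defined in
kept-window index space: windows removed by the coverage filter do not break
a run, because filtering removes observations, not genome. Five 300-bp
windows set the minimum detectable CNV at 1500 bp.

A note on extension: because moving the state-switch point one window does
not change the number of transitions, a run bordered by a noise window whose
coverage crosses the emission midpoint is extended at no transition cost.
A 4-window amplification therefore has a small (~10⁻³ per flank per
realisation at 30×) probability of surfacing as a 5-window call that juts
one window beyond it; the minimum-size rule guarantees only that no call
lies within a sub-five-window span.

The likelihood-ratio filter compares the product of per-window emission
densities at the decoded states against a constant-baseline null (copy
number 2, or 1 on the male X — the diploid statement generalised to the
haploid chromosome), computed in log space; calls below ratio 1000 are
dropped, the boundary value kept (with a 10⁻⁹ log-space tolerance so an
exactly-boundary ratio is not lost to rounding). Deletions are modelled as
states but not emitted as calls; amplifications are the product.

Sample QC removes samples whose normalized-coverage variance over autosomal
kept windows exceeds 0.2. At 30× Poisson noise the expected variance is
(2/√30)² ≈ 0.13, so the threshold tolerates moderate over-dispersion but
rejects erratically covered samples (and, by the same mechanism, samples
carrying very large high-copy amplifications).

## Validation simulations

The shuffle null permutes each sample's kept-window normalized coverage and
reruns the whole calling chain; surviving calls are false by construction.
Permutation is **within chromosomes**: pooling across chromosomes would put
diploid autosomal values (~2) onto the haploid male X, where they exceed the
baseline of 1 and manufacture amplified runs that say nothing about the
caller. The sensitivity simulation plants a single amplification of given
length and copy number into a synthetic diploid background and reports the
fraction of realisations in which a surviving call overlaps it. Problem
sizes in the shipped tests (e.g. 50 samples × 5000 windows × 20 shuffle
repetitions; 200 sensitivity repetitions on 2000-window genomes) were chosen
as the smallest that estimate the rates stably.

## Cohort matching and frequency filter

The pairwise relation "both breakpoints within one window" is not
transitive, so matching is anchor-based and greedy: calls sorted by
(chromosome, start, end, sample) are scanned once; each call joins the
earliest-seeded variant whose anchor call it matches, else seeds a new one.
This is deterministic, order-independent given the sort, and partitions the
call set. Consensus coordinates are medians of member starts/ends. The
frequency filter keeps a variant if any population reaches 5% carriers
(populations of ≥40 QC-passed samples) or 3 carriers (smaller populations);
population sizes are evaluated on QC-passed samples.

## Enrichment nulls

The position null re-places each variant uniformly among all runs of k
consecutive kept windows on **its own chromosome** (k = its observed
kept-window footprint), which holds chromosome composition and the kept-window
landscape fixed; the euchromatin-restricted variant excludes placements
overlapping heterochromatin. Heterochromatin membership is any-overlap (one
base suffices; touching half-open intervals do not overlap). Gene content
uses two literal rules: a gene is retained when at least half of its windows
are kept, and a retained gene is "copied" when all its kept windows lie
inside the variant — dropped windows extending beyond the variant do not
disqualify it. The gene-identity null reassigns each genic variant a
uniformly random run of the same number of consecutive retained genes, never
crossing a chromosome boundary; a variant counts once however many detox
genes it covers. Two-tailed p-values double the fraction of simulations
reaching the observed count, capped at 1; when no simulation reaches it the
p-value is reported as the resolution bound 2/n_sims. Contingency tables are
tested by Fisher's exact test, falling back for tables larger than 2×2 to a
Monte-Carlo p-value with tables drawn under fixed margins (Patefield
algorithm) and the tail ordered by table probability, with 10⁶ replicates by
default.

## CNV alleles

Read-pair classification: cross-mapped (mates on different chromosomes or
mate flagged elsewhere), same-orientation (equal strands), face-away
(leftmost mate on the minus strand), long-insert (proper orientation, insert
beyond mean + 5 SD of the library model), else proper. Diagnostic-read
support requires the classified pattern to match the signature and the mate
coordinates to fall within anchor tolerances (±300 bp for pairs, plus one
read length of slack at the right anchor where the mate's alignment start
sits; ±10 bp for soft-clip positions). Presence requires two diagnostic
reads — one chimeric fragment can mimic any pattern, two independent ones at
the same breakpoints rarely do.

Allele-specific copy number solves a non-negative least-squares model in
which each allele contributes its copy gain over its span; alleles with
identical window footprints in a sample are non-identifiable from coverage
alone and are flagged rather than guessed. Estimates are rounded half-up;
as a cohort-level guard, when exactly one sample's rounded copies exceed 2
while its raw estimate is below 3.0, that lone estimate is treated as noise
and recorded as 2 (flagged). Genotyping maps copies 0/1/2 to homozygous
wild-type/heterozygous/homozygous; an allele with copies above 2 anywhere
cannot be phased and is excluded, and when every carrier has exactly 2
copies and none has 1 the allele is interpreted as a pure triplication with
carriers genotyped heterozygous. Hardy-Weinberg consistency is tested with
the exact conditional (Levene–Haldane) distribution, two-sided by
probability ordering, at α = 0.05 per population where the allele occurs,
without multiplicity correction — a deliberate, conservative screen, flagged
as such.

## Selection scans

EHH for a core allele is the fraction of unordered carrier pairs identical
at every included SNP from the CNV-region edge out to distance x, computed
independently leftward and rightward with SNPs inside the region masked
(genotyping inside an amplification is unreliable). Pairs (without
replacement) rather than allele counts are used; at the carrier counts
involved the difference is O(1/n). Shared haplotype length per pair and side
is the distance to the last concordant SNP before the first discordant one
(zero if the nearest SNP differs; the full surveyed span if none does), and
the reported distribution sums the two sides. The 95% CI on the median is a
percentile bootstrap over pairs (1000 resamples, seeded); resampling pairs
rather than haplotypes is a pragmatic choice — pairs are the sampling unit
of the statistic — and is the documented alternative to a haplotype-level
bootstrap.

Clustering uses the proportion of accessible SNPs differing between
haplotypes over the first 1000 SNPs of the supplied matrix, complete-linkage
agglomeration, and flat clusters cut at height 0.001; complete linkage
guarantees every within-cluster pair differs at no more than the cutoff
fraction of SNPs. Labels are assigned by decreasing cluster size (ties by
smallest member index), so cluster 1 is always the largest. Cluster–CNV
association is evaluated at the sample level: Spearman rank correlation (and
least-squares slope of cluster-haplotype count on copy number — slope 0.5
means two copies per swept chromosome, i.e. a triplication) in females, and
a 2×2 Fisher exact test of cluster presence against allele presence in
males, whose single X makes counts binary.

## Synthetic-data generator

The generator emulates: fixed-size window tiling with GC% drawn from a
normal distribution (mean 45, SD 8, matching the unimodal mid-40s GC of
mosquito genomes) rounded to integer percent; accessibility mostly 1 with a
small fraction of degraded windows; MQ0 fractions mostly near zero with
occasional ambiguous windows; heterochromatin at chromosome ends; gene
models laid left to right with a detox flag; per-sample mean depth 30× (the
cohort design target) with negative-binomial counts (variance = dispersion ×
mean; dispersion 1 = Poisson) and a quadratic GC bias peaking at 45%;
haploid male X; planted tandem duplications, tandem inversions and
internal-deletion amplifications with known copies and zygosity;
breakpoint-spanning read pairs and soft-clips consistent with each
mechanism (at least two per planted allele, matching the presence rule's
premise); and haplotypes in which carriers of a CNV allele copy a founder
haplotype out to exponentially distributed break distances.

It does **not** emulate: base-level sequence or alignment, recombination
maps, linkage between unlinked variants, population structure beyond labels,
accessibility-driven coverage loss, batch effects, or reference errors.
Passing tests therefore demonstrate the pipeline's correctness and
calibration under its own model assumptions — Gaussian-ish noise around
integer copy levels after GC normalization — not robustness to every
artifact of real alignments. Coverage means are deliberately independent of
the accessibility track so that normalization calibration can be verified
exactly; in real data low-accessibility windows also lose coverage, which is
one reason the normalization excludes them from its constants.

## Degenerate inputs and numerical conventions

All coordinates are 0-based half-open; a trailing partial window is dropped.
Empty window sets decode to empty paths; a zero or undefined normalizing
constant yields NaN normalized coverage and the window is excluded from
analysis; likelihood ratios are always computed in log space (a zero null
likelihood keeps the call). Bootstrap CIs are clamped to contain the point
median. All stochastic components take explicit seeds and are reproducible
bit-for-bit under a fixed seed.

## Known limitations

Signature discovery is declarative: the package scores samples against
supplied diagnostic signatures but does not discover signatures from data
(a manual step in practice). Phasing of CNV genotypes onto haplotype
scaffolds is consumed as input, not performed. Deletions are not emitted as
calls. The HMM assumes a shared variance profile across chromosomes within
a sample; strong chromosome-specific biases would violate it.
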