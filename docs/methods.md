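# Methods

## The analysis problem

Compartment-fractionation mitomiR profiling pools RNA from many animals
(equal molar amounts) into one sequencing library per group, trading
replication for depth. The design leaves two statistical problems that this
package addresses end to end:

1. **Unreplicated differential expression.** With one library per
   condition, each observed count is modelled as Poisson around a
   library-size-scaled relative abundance. Conditioning on the summed count
   n = x₁ + x₂ removes the nuisance scale: under equal relative abundance,
   x₁ | n ~ Binomial(n, π) with π = N₁/(N₁+N₂). This conditional binomial
   is the "exact Poisson test".
2. **Cytosolic contamination.** The purified mitochondrial fraction always
   carries residual cytosolic RNA, so a rise in the fraction can reflect
   cytosolic upregulation. The cross-compartment rule therefore demands a
   mitochondrial rise *and* a flat-or-falling whole-tissue level.

## Exact test

The two-sided p-value uses the minimum-likelihood convention: the sum of
all binomial point masses not exceeding the observed one. This is the
common convention for exact two-sided binomial tests (scipy's `binomtest`
uses it too, and the test suite cross-checks against it); a
doubled-smaller-tail variant is available as
`de.exact_poisson_test_doubled`. n = 0 returns p = 1.

Implementation: full pmf enumeration for n ≤ 1024; above that, unimodality
of the pmf makes the acceptance region two tails, so the observed side is a
direct cdf/sf call and the far boundary is found by binary search on the
monotone slope (O(log n)). The two paths agree with brute-force enumeration
to < 1e-10 across the switch point. Point masses are compared with a 1e-12
relative tie tolerance so floating-point rounding cannot split exact ties;
when the modal mass itself falls inside the cutoff the p-value is exactly 1.

Fold changes are log₂ CPM ratios with a 0.5-CPM pseudocount on both sides
(configurable); a double-zero row with pseudocount 0 yields a missing fold
change (NaN), never ±∞, and is called `ns`. Calls use strict inequalities
(fold > 2 / fold < 0.5) and raw p < 0.05 by default, since published
per-miRNA tables of this design report raw exact-test p-values; `use_q=True`
switches the same rule to BH q-values. BH adjustment goes through
statsmodels' step-up implementation and is verified against the textbook
definition on random vectors.

Pairwise profiling keeps a miRNA for a condition pair iff it has ≥ 1 read
(`min_count`) in at least one of the two libraries — a permissive detection
rule appropriate for pooled deep libraries. Heatmap ordering uses
average-linkage agglomeration under 1 − Pearson distance, the most common
heatmap convention; zero-variance rows cannot be correlated with anything,
get the maximal distance (2.0) with a warning, and are placed last in the
returned leaf order.

## ΔΔCt

Triplicate Ct values are aggregated by arithmetic mean (no outlier
rejection; triplicates spreading > 0.5 cycles only trigger a warning), ΔCt
is target minus reference within a sample, ΔΔCt the between-condition
difference, and fold change 2^(−ΔΔCt) under perfect doubling efficiency.
Efficiency correction and standard curves are out of scope. Swapping
treatment and control inverts the fold change exactly.

## MitomiR rule

`enriched` ⇔ mitochondrial fold > 2 ∧ (p < 0.05 where a p exists) ∧
whole-tissue fold ≤ 1 + 0.2. The 0.2 "unchanged" tolerance is a declared
operationalization — qualitative judgements of "decreased or unchanged"
have no numeric criterion — and is configurable. Mitochondrial evidence can
come from sequencing DE or qPCR; when both exist, qPCR wins (it is the
validation instrument and carries no sequencing-side biases). Candidates
with a missing required input are `indeterminate`. No multiple-testing
adjustment is applied across the (small) candidate list at this stage.

## Pathway enrichment

Targets of the input miRNAs with score strictly > 0.9 are pooled into one
union gene set; each pathway of size K in a universe of size M is tested
with the hypergeometric upper tail P(overlap ≥ k) for a target set of size
n; BH across pathways; significance at q < 0.05. The union-set single-test
formulation matches the default behaviour of the widely used mirPath-style
tools; per-miRNA p-value merging modes are not implemented. The default
universe is all genes in the pathway collection. Reports rank by ascending
p with lexicographic tie-breaks and carry the number of contributing miRNAs
and distinct target genes per pathway.

## Synthetic data

The generator emulates the pooled design: a log-normal baseline abundance
vector (natural-log μ = 0, σ = 1.5 — heavy-tailed, the standard stylized
fact for miRNA abundance), per-condition pools obtained by multiplying
planted mitomiRs by 2^effect and renormalizing, and one library per
(compartment, condition) with expected counts = library size × pool
composition. The mitochondrial library's composition is the contaminated
mixture (1−φ)·mito + φ·total. Defaults describe the targeted study
conditions: 300 miRNAs, 2×10⁶ reads per library, 20 planted mitomiRs,
mitochondrial log₂ effects (3, 1) for the early and late stages, whole-
tissue effects (0, 0), φ = 0.2 (purification reduces but does not remove
cytosolic RNA; a moderate default exercises the classifier), Poisson counts
(dispersion 0, matching the exact test's model; a gamma-Poisson option with
variance m + d·m² exists for robustness stress tests). φ = 1 is accepted as
the degenerate full-contamination limit, where the mitochondrial library's
expected composition equals the whole-tissue one exactly.

qPCR simulation uses Ct = 8 − log₂(measured abundance) plus Gaussian
replicate noise (default SD 0.1 cycles, a typical intra-assay triplicate
repeatability), with a U6-style reference held at constant abundance. The
annotation generator gives every miRNA 25 high-score target edges (plus 10
sub-threshold decoys); planted mitomiRs draw 80% of targets from one
planted pathway of 40 genes in a 2,000-gene universe split into 40
pathways.

All randomness flows from the single config seed through named
`numpy.random.default_rng` substreams (counts / qPCR / annotation), so
identical configs are bit-identical and stages can be re-run independently.

What the simulation does *not* model: read-level artifacts (adapter
trimming, mapping multi-hits, isomiRs), compartment-specific baseline
composition differences at sham (both pools share one baseline), reference-
gene instability, and cross-pathway gene-set overlap structure. Passing
recovery tests therefore demonstrates correctness of the statistical chain
under its own model, not robustness to those real-data artifacts.

## Problem sizes and numerical choices

The test and acceptance workloads use the default study conditions (300
miRNAs, 2×10⁶-read libraries) for recovery runs, 20 seeds for averaged
recovery metrics, 10,000 replicates for null-calibration and power
monotonicity checks, and complete enumeration oracles up to n = 50
(binomial) and M = 60 (hypergeometric) — sizes at which the brute-force
definitions are exact and fast. Exact-test p-values are clamped to [0, 1];
hypergeometric tails use `scipy.stats.hypergeom.sf(k−1, …)` so k = 0 gives
p = 1; enrichment of an empty target set is well defined (all p = 1).

## Known limitations

- The conditional test is exact only under Poisson sampling of pooled
  libraries; overdispersed (animal-to-animal) variation makes it
  anti-conservative, which is inherent to the unreplicated design.
- The classifier compares point estimates of fold change against fixed
  thresholds; it propagates no uncertainty from the qPCR side.
- The enrichment universe choice (pathway collection vs target map) shifts
  p-values; both options are exposed but only one default is exercised.
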