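# Methods

## Design being modelled

The package analyses a replicated experimental-evolution design: a single
base population is split into four replicate pairs of lines, one line per
pair evolving under elevated polyandry (E) and one under enforced monogamy
(M), for on the order of 160 generations at an effective size of about 120
per line. One pool of 40 females per line is then sequenced
(pool-seq), so allele frequencies are observed through two layers of
sampling — individuals into the pool, reads from the pool. Five
chromosome arms are tracked; two (`XL`, `XR`) are X-linked and drift with
`round(1.5·N_e)` gene copies instead of `2·N_e` (females-only pools still
contribute two X copies per individual). X-linkage is configuration (a set
of chromosome names), never inferred.

## The divergence scan

Per biallelic SNP, the major-allele frequency of each pool (major allele
defined across all pools) is regressed on treatment with a
binomial-logit GLM and a free quasi-likelihood dispersion. With a single
binary predictor the IRLS solution is closed-form: the fitted group
frequency is the (weight-)mean pool frequency per treatment and the
treatment coefficient the difference in group log-odds. The dispersion is
Pearson χ²/(n_pools−2), not floored at 1; the test is two-sided t with
n_pools−2 df and dispersion-scaled variance. The test suite verifies this
closed form against an independently fitted GLM to 1e-6.

Two substantive choices deserve note:

* **Response weighting.** The default treats each pool's *frequency* as
  one unweighted observation (`weights="none"`), the conventional way a
  quasibinomial proportion model is fitted. A count-weighted variant
  (`weights="counts"`) is available. The unweighted fit is the right
  default for this design: between-pool variance is dominated by drift,
  which does not scale with read depth, and the count-weighted fit
  essentially discards pools near fixation (their binomial weight
  `r·μ(1−μ)` vanishes), destroying power exactly where consistent
  divergence is strongest.
* **Zero-count rule.** If any major or minor count of a SNP is zero, 1 is
  added to every major and minor count of that SNP (all pools); a
  per-pool-only variant is available behind a switch.

P-values convert to q-values by the Storey–Tibshirani procedure: π̂₀(λ)
on λ ∈ {0, 0.05, …, 0.90}, smoothed by a natural cubic regression spline
with 3 degrees of freedom (knots at the grid range thirds), evaluated at
λ = 0.90, clipped to (0, 1]; q is the backward running minimum of
π̂₀·m·p(j)/j. Top SNPs (q < 0.05) chain into clusters by single linkage
with an inclusive 50 kb gap; clusters exceeding a member threshold
(default 10) are "peaks". Treatment labels can be permuted genome-wide
(one shared relabelling per permutation, preserving cross-SNP
correlation; C(2k,k)−2 unique assignments, 68 for 4-vs-4, excluding the
observed assignment and its complement) or independently per SNP.
The per-chromosome excess of top SNPs is tested with an exact binomial
against each chromosome's share of background SNPs (Bonferroni across
chromosomes); the method is a documented choice, as is the χ² alternative
it could be swapped for.

## SNP calling

A site is kept when its A/T/C/G coverage summed across pools is ≥ 18
("more than 17") and strictly below the per-chromosome 95th percentile of
summed coverage (linear-interpolation quantile); an allele is called when
its pooled count is ≥ 17 (">16") and its pooled frequency > 0.001.
"Across all pools" is read as summed/pooled throughout; a per-pool
coverage variant exists behind a switch because the original tool's
behaviour is not decidable from its description. Sites with more than two
called alleles are dropped and tallied rather than truncated to two.
N and deletion counts never enter coverage. Note one interaction: because
tri-allelic sites are dropped, raising the allele-count threshold can
occasionally *increase* the SNP count (a dropped tri-allelic site becomes
biallelic); monotonicity holds on biallelic sites.

## Diversity and differentiation

Site π uses the two-stage correction `C/(C−1) · 2p̂(1−p̂) · 2n/(2n−1)`
(read sampling with replacement from 2n pool chromosomes, pool sampling
from the population); sites with coverage < 2 are skipped. Windows are
50 kb at a 40-kb step ("50 kb with a 10-kb overlap" taken literally; a
step flag allows alternatives), trailing partial windows kept and
flagged. Window π divides the summed site π by window length (or by a
supplied covered-site count); θ_W = S/a₁ and Tajima's D use the classical
constants at sample size 2n (n = diploid pool size), with D reported only
when the window holds at least `min_snps` (default 10) segregating sites.
Gene-level values are unweighted means over all windows intersecting the
gene span by ≥ 1 bp. Diversity is estimated per pool and averaged per
treatment afterwards.

Pairwise pool F_ST per SNP uses identity probabilities: within-pool
identity is de-biased for reads resampling the same chromosome
(`Q̂₁ = (n·rp − 1)/(n − 1)` with rp the read-pair identity and n the pool
chromosome count) and for finite pool size; between-pool identity needs
no correction; `F_ST = (Q̂₁−Q̂₂)/(1−Q̂₂)`. Negative values are retained in
window means (clamping would bias means upward). A simpler count-based
(Karlsson-style) estimator is available for sensitivity analysis. The
neutral X expectation `F_X` uses the closed form given in the README; the
final term is a *product*, `(1−F_A)(7z−1)` — the reading under which
F_X(0, z) = 0 — and the test suite pins it against an exact rational
evaluation. Bootstrap bands resample, per iteration, as many windows as
there are autosomal windows from the set of *all* windows (a flag
restricts to autosomes only); X:A ratios bootstrap within strata.

## Linkage disequilibrium

r² is computed by direct two-locus haplotype counting over read pairs
that cover both SNPs (adequate at within-fragment distances; no EM).
Site filters (MAF > 0.1, coverage 10–400, base quality > 20) are
evaluated on the read observations themselves. Distance classes are exact
base-pair distances by default with a minimum of five SNP pairs per
class; a bin-width flag pools neighbouring distances (the pipeline uses
width 10) because desk-scale SNP-pair counts per exact distance are far
below those of a ~2M-SNP genome. The decay fit is OLS of mean r² on
natural-log distance (the log base only rescales the slope); slope
contrasts across regions/treatments come from a class-level linear model
with region and treatment interactions with log-distance.

At the simulated timescale (~160 generations from a common base), LD at
read-pair range is built by drift and barely eroded by recombination
(r·d per generation ≤ ~2×10⁻⁵ at 300 bp), so fitted decay slopes on
synthetic data are near zero. This is the expected behaviour of the
model, not a defect; decay-slope *recovery* is tested with planted
class-level data, and the recombination sensitivity of the slope with
scaled-up rates.

## Expression integration

Genes within 10 kb (inclusive; 1 Mb variant available) of any top SNP
form the query set; its overlap with the DE gene set is compared with
1000 resampled gene sets of equal size drawn without replacement from the
annotation. Significance follows the 95th-percentile rule; an
add-one-corrected empirical p is reported alongside (never exactly zero).
DE/non-DE contrasts reduce the non-DE stratum to its mean and test DE
values against that constant with a one-sample signed-rank test (the
statistic reported as V); a two-sample rank-sum mode exists. The
rank-sum-against-a-constant formulation in the source description is
internally inconsistent (a rank-sum test needs two samples), which is why
the one-sample signed-rank reading is the default. The sex-bias ANCOVA
fits ΔSB = log₂FC_E − log₂FC_M on chromosome type, Tajima's D per
treatment, and both interaction blocks, with sequential (type-I) F tests
per term; chromosome types with fewer than two records raise an error.

## The synthetic-data generator

Most loci are simulated as freely recombining sites: deterministic
viability selection (fitnesses 1, 1−hs, 1−s; dominance h = 0.5 by
default) followed by binomial drift, all lines sharing identical starting
frequencies drawn once from Uniform(0.05, 0.95) (the ancestral spectrum
is not known; this default is configurable, not a claim). Divergent
selection is **antagonistic by default** (`s_m = −s_e`): one-sided
selection leaves M lines scattered by drift and cannot produce the
consistent fixed E/M differences the design is known for.

Linkage is simulated only inside declared haplotype regions: a full
haplotype population per line with per-interval recombination
(probability `rate · bp` between adjacent loci), genic selection `h·s`
per copy at the region's selected locus, optional mutation (allele flips
at a per-locus rate), and a shared ancestral pool that is either at
linkage equilibrium or composed of a finite number of founder haplotypes.
Founder structure supplies ancestral LD; without it a sweep drags nothing
and produces no clustered divergence. Region markers stand in for
kb-scale segments, so the default region mutation rate (2×10⁻⁴ per
marker per copy per generation in the canonical scenario) is an
aggregated, scaled rate chosen to deliver the young low-frequency
variants post-sweep diversity statistics respond to.

Pool-seq sampling is two-stage: `2·pool_size` allele copies per pool
(whole haplotypes drawn without replacement inside regions, binomially
elsewhere), then Poisson read depth (negative-binomial optional) and
binomial allele reads. Fixed seeds give byte-identical sync output.

The canonical scenario (`simulate.divergent_scenario`) places ~5k loci on
five arms (1% under ±0.1 antagonistic selection), three 150-kb sweep
regions (chromosome 3, XL, XR; rare favoured variant at starting
frequency 0.1; six founder haplotypes) and two dense 20-kb neutral
regions at ~100-bp marker spacing for read-pair LD. Chromosome lengths
(450–600 kb) and locus counts are desk-scale stand-ins for real arms;
the founder count was chosen so the simulated top-SNP architecture
matches the published pattern for this kind of study — the majority of
top SNPs concentrated in a few multi-SNP peaks — which larger founder
numbers (or a linkage-equilibrium ancestor) fail to produce.

### What the generator does not emulate

Sequence-level reads (mapping error, base-composition bias), indels and
inversions, gene conversion, background selection outside declared
regions, genome-wide linkage (loci outside regions are independent, so
clustering of *unselected* hitchhikers cannot arise there), and a
realistic ancestral site-frequency spectrum. Passing tests therefore
demonstrate correctness of the estimators and the qualitative logic of
the scan on this model, not performance on real libraries.

## Calibration results and known limitations

* On fully neutral data the scan's p < 0.05 fraction sits near 0.02 —
  mildly conservative, as expected for a t test on 6 df with estimated
  dispersion — and q < 0.05 makes essentially no discoveries.
* Recovery of selected loci at s = 0.05 is intrinsically limited by
  drift at N_e = 120 over 160 generations: drift variance is
  ~0.49·p(1−p) while the deterministic displacement is only ~4 logits,
  so a substantial fraction of selected loci end inconsistently across
  replicates and no q < 0.05 rule can call them. The package reports
  measured recovery honestly (~30% under those conditions at near-zero
  false-top rates); with s = 0.1 recovery roughly doubles.
* Tajima's D on drifted standing variation (no genome-wide mutation) is
  strongly positive everywhere (~+2.4); contrasts (swept vs unswept) are
  meaningful, absolute levels are not comparable to equilibrium
  populations.
* The pool-seq detection floor (pooled allele count ≥ 17) hides
  line-private rare variants, biasing pooled D upward in exactly the
  regions where rare variants are the signal; the haplotype-oracle test
  runs at deep coverage with a lenient caller for that reason.

## Numerical choices

Quantiles use linear interpolation (numpy default). Cluster linking is
inclusive at exactly 50,000 bp. The GLM returns p = 1 for exactly
balanced SNPs (β = 0) even when φ = 0, and p = 0 for perfectly
consistent divergence (φ = 0, β ≠ 0). Undefined F_ST (both pools fixed
for the same allele, or coverage < 2) propagates as missing and is
excluded from window means. Empirical overlap p-values carry the add-one
correction. The pipeline derives one sub-seed per stage from the global
seed via a stage-name hash, so stages rerun independently yet
reproducibly; reruns with the same seed are byte-identical.

## Problem sizes

Default simulations use ~5–6k loci over 2.5 Mb of genome, chosen so a
full pipeline run takes ~20 s and the complete validation suite minutes
on one CPU; all sizes scale through `SimulationConfig`/`RunConfig`.
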