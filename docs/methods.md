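# Methods

## Synthetic data model

`simdata` draws, per locus, an ancestral alternative-allele frequency
p₀ ~ U(0.05, 0.95), then applies a two-level Balding–Nichols hierarchy:
each clade draws an intermediate frequency from Beta(p(1−F)/F, (1−p)(1−F)/F)
with clade-level drift F = 0.02, and each species drifts from its clade's
intermediate with a terminal F. Defaults mirror the qualitative structure of
the target system: the clades are {CAM}, {PAL, SUD} and the weakly
differentiated DET clade {TAU, DIF, EXS}; terminal F is 0.05 inside DET and
0.15 elsewhere. Degenerate frequencies (0 or 1) are propagated unchanged.
Admixture edges replace the recipient's frequency with
(1−m)·p_recipient + m·p_donor.

Polyploids are sums of independent Hardy–Weinberg subgenomes:
allotetraploid dosage = Bin(2, p_A) + Bin(2, p_B) (disomic, no homoeologous
exchange), autotetraploid dosage = Bin(4, p) (tetrasomic), allohexaploid =
three Bin(2, pᵢ) draws. Ground truth records the per-sample subgenome
decomposition, which sums to the total dosage by construction. When both
parents share a frequency, Bin(2,q)+Bin(2,q) = Bin(4,q): allo- and
autotetraploids are then distribution-identical, the known indistinguishable
case; tests assert the classifier does *not* call this case disomic.

Read depths are Poisson(λ = 60 by default, roughly RADseq coverage after
dedicated polyploid sequencing; a negative-binomial option with dispersion r
exists, off by default) with alternative-read probability
π = (d/k)(1−ε) + (1−d/k)ε for dosage d, ploidy k and base error ε = 0.01.
Missing genotypes are injected post hoc at rate 0.1. SNP positions are
placed with ≥ 150 bp spacing (mean gap ≈ 575 bp) so locus thinning and the
1000-bp LD window are meaningful; RAD locus ids group SNPs in 500-bp bins.

What the generator does **not** emulate: coalescent gene trees and linkage
(loci are exchangeable given the frequency hierarchy), allele dropout,
base-quality error profiles, and paralog collapse. Passing tests therefore
demonstrate correctness of the inference machinery under the declared
frequency model, not robustness to every RADseq artifact.

For parent-inference studies a helper configuration adds a NIV outgroup
(its own clade, terminal F = 0.30) so locus trees can be rooted; the
six-species default is otherwise unchanged.

## Filtering

Filters run in a fixed order — genotype depth mask (minDP 8/30/40 by ploidy
2/4/6, maxDP 200), site missingness ≤ 0.5, minor allele count ≥ 3, observed
heterozygosity ≤ 0.65 — because depth masking changes the site statistics
the later rules use. The heterozygosity rule is computed over diploid
samples only by default (`het_ploidies=(2,)`); it is a diploid-dataset rule,
and whether it should extend to polyploid genotypes is a user decision.
RGS→ploidy calls follow the observed fluorescence-ratio bands (0.21–0.29
diploid, 0.47–0.60 tetraploid, 0.77–0.84 hexaploid); gap values are flagged
putative-3/putative-5, values outside [0.15, 0.95] unknown, and the narrow
unobserved margins adjacent to the diploid and hexaploid bands are assigned
to the neighboring even ploidy.

## Inheritance-mode classification

Curves use allele-frequency bins of width 0.05 and a site-count-weighted
3-bin moving average (simple smoothing, not loess). The excess statistic Δ
is the weighted mean over bins with centers in [0.35, 0.65] (≥ 10 sites per
bin) of observed G_{k/2} minus the Binomial(k, q) expectation at the bin
center. Thresholds — disomic at Δ ≥ 0.15, tetrasomic at Δ ≤ 0.05 — were set
by simulation calibration (clearly separated: constructed disomic
populations with 35% strongly differentiated loci give Δ ≈ 0.28, tetrasomic
populations Δ ≈ 0.00) and are reported with every call. Allotetraploids of
*weakly* diverged parents fall below the disomic threshold; this is a
property of the data, not the classifier — disomy is only visible through
subgenome-fixed differences. Hexaploid curves use k = 6 classes with the
same machinery and should be treated as experimental.

The individual-level classifier retains sites with 30 ≤ depth ≤ 200 and
minor read count ≥ 3 and fits, by EM, three Gaussians with fixed means
0.25/0.5/0.75, shared free variance and free weights, plus a uniform
background on (0,1) whose weight is capped at 0.2 (a denoising stand-in;
the capped M-step is the constrained maximizer, so the log-likelihood is
non-decreasing). Calls: allo-like at w(0.5) ≥ 0.6, auto-like at
w(0.5) ≤ 0.45. Profiles with < 50 sites are flagged unreliable; EM stops at
500 iterations or an absolute log-likelihood gain < 1e-8.

## Genomic polarization and parent inference

Polarization is a per-column rule over the 16-symbol IUPAC alphabet: a
two-allele ambiguity code whose set contains the single, unambiguous
reference base becomes the other allele; everything else (homozygous bases,
reference not among the alleles, reference N/gap/ambiguous, polyploid
N/gap) is unchanged. The production implementation is a 16×16 lookup table;
tests verify exact agreement with a per-column set-arithmetic oracle, and
idempotence under a fixed reference.

Chromosomes are split into 20 regions of equal SNP counts (floor/ceil, the
larger blocks first), with boundaries midway between adjacent SNPs of
neighboring blocks — six chromosomes give 120 regions. Per region,
neighbor-joining locus trees are built on the ambiguity-aware p-distance
(match score = |allele-set intersection| / |allele-set union|; columns with
N or a gap in either sequence excluded; negative NJ branch lengths clamped
to zero), rooted on the outgroup. The half-match for heterozygote-vs-base
comparisons preserves shared-polymorphism signal, which matters when
candidate species are weakly differentiated; an `ambiguity="missing"` mode
is available. The species-tree summary is a greedy majority-rule consensus
(clades accepted in decreasing frequency when compatible; support = clade
frequency) standing in for a quartet-based supertree; tree engines are
pluggable — externally computed newick trees can be fed to the
pairing/iteration layer.

The iteration starts from a configured reference (CAM by default), uses one
representative individual per species (highest call rate, overridable),
polarizes the focal tetraploid in every region, and takes the focal's
sister in the summary tree as the next reference; a sister that is a named
clade (e.g. DET) is resolved to the member species with the most
species-level locus-tree pairings (ties alphabetical). Convergence is
declared when the unordered {reference, sister} pair repeats between
consecutive rounds; that pair is reported as the parents, with a full
per-iteration audit (reference, pairing counts, summary newick). A
reference cycle without repetition within `max_iter` (6) returns no parents
plus the trajectory. Hexaploids are rejected: the two-allele rule assumes
exactly two subgenomes.

**Known limitation.** When one candidate parent belongs to a weakly
differentiated clade, the per-region pairing signal for the *second* parent
is marginal. After polarizing a TAU×PAL tetraploid against PAL under the
default divergences, the genome-pooled distance from the polarized focal to
TAU beats the nearest DET competitor by only ~0.003–0.005 — about 1–2
standard errors — so 120-region sister votes recover both parents in
roughly 40–75% of replicates rather than always, and occasionally lock onto
a DET clade-mate of the true parent or converge prematurely onto the
{start-reference, first-sister} pair. This mirrors the behavior seen on
real data, where polarized tetraploids pair with the whole DET clade rather
than a single species. Design alternatives evaluated and rejected: masking
residual-heterozygous focal columns, log-corrected distances,
minimum-distance votes, and species-consensus reference or tip sequences
(consensus tips destroy the shared-polymorphism signal entirely). More
SNPs, more divergent candidates, or ML locus trees on longer regions are
the real remedies.

## Relatedness

r₍ₓᵧ₎ = Σₗ(xₗ−pₗ)(yₗ−pₗ)/Σₗ pₗ(1−pₗ) over loci non-missing in both samples
with 0 < pₗ < 1, where xₗ is dosage/ploidy and pₗ the ploidy-weighted global
frequency (optionally excluding the focal species to reduce circularity).
This is a correlation-type moment estimator chosen because only *relative*
rankings of candidate progenitors are used downstream; absolute values are
not comparable to other estimators' scales. The vectorized implementation
is tested to 1e-10 against a per-pair, per-locus loop. Wilcoxon rank-sum
p-values are exact (enumeration with midranks) for n₁+n₂ ≤ 12, otherwise
normal with tie and continuity corrections; fully tied data give p = 1.

## D-statistic

Frequency-based ABBA/BABA terms per locus; D = Σ(ABBA−BABA)/Σ(ABBA+BABA);
loci with any missing frequency or zero denominator contribute nothing.
Significance uses a Busing-style weighted delete-one block jackknife over
consecutive 100-SNP blocks (weights = block denominators); SE = 0 (identical
blocks) is reported as Z = ±inf. Calibration under the generator: with the
trio (TAU, DIF, PAL) and the NIV outgroup at 5000 SNPs and 25 samples per
species, the null false-positive rate at |Z| ≥ 3 is ~0/20 and power against
m = 0.2 PAL→DIF admixture is ~20/20, with mean D ≈ 0.04.

## Simulation sizes

Unit tests run small (hundreds of loci, ≤ 50 samples). The calibration
suites use 50-sample populations at 5000–6000 SNPs; the parent-recovery
study uses 20 replicates (6000 SNPs, 50 samples/species) in the test suite
and 10 in `scripts/acceptance.py`, whose full run takes about a minute on
one core. All randomness is seeded; identical configurations produce
byte-identical simulated outputs.
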