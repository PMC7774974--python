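# Methods

This note documents the statistical models implemented in `perupop`, the
conventions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Markers and coordinates

All genomic coordinates are 1-based inclusive in the rCRS frame (the
16,569-site human mitochondrial reference). Site masks are applied as a
`restrict` range intersected with the covered positions minus `exclude`
ranges; the canonical masks are the poly-C tracts 303–315 and
16184–16193 (13 + 10 sites) and the coding-region restriction 577–16023
(15,447 sites). Masking never alters sequence content — statistics
consult the active-site set only — and is idempotent.

Missing data are `N`/`-` in sequences and empty cells in tables.
Heteroplasmies and ambiguity codes are treated as missing. All pairwise
statistics use pairwise deletion: a site (or locus) is skipped for a pair
when either member is missing there. This maximizes data use and mirrors
the behavior of the standard desktop tools for these statistics.

## Diversity statistics

Haplotype diversity uses the unbiased estimator
h = (n/(n−1))(1 − Σ pᵢ²) over distinct-haplotype frequencies.
MNPD averages, over all C(n, 2) pairs, the number of differing active
sites (sequences) or differing loci (STR haplotypes). π is per-site: the
mean over pairs of differences divided by comparable sites for that pair.
Sequence differences count substitutions only; gap columns are missing.
n < 2 renders all three undefined and they are reported as missing.

## AMOVA and fixation indices

The decomposition operates on squared inter-individual distances δ²ᵢⱼ:
the number of differing active sites for sequences (Φ_ST), the sum of
squared repeat differences for STR haplotypes (an R_ST-like metric, with
number-of-differing-loci as a configurable alternative), and the
allele-sharing distance for autosomal genotypes. Total sums of squares
are partitioned into among-group, among-population-within-group and
within-population terms; variance components use the standard
n-coefficient weighting for unequal sample sizes, and indices are
F_CT = σ²ₐ/σ²_T, F_SC = σ²ᵦ/(σ²ᵦ+σ²_c), F_ST = (σ²ₐ+σ²ᵦ)/σ²_T. Negative
components are reported as computed, never truncated, and percentages
are taken from the raw components.

Significance uses three permutation schemes: whole populations among
groups (F_CT), individuals among populations within groups (F_SC), and
individuals among all populations (F_ST), with the positively biased
estimator p = (b+1)/(B+1) so that finite B never yields p = 0. The
default is B = 10,000 permutations and a mandatory seed; permutations of
individuals (not haplotypes) were chosen as the exchangeable unit. A
completely invariant sample is flagged `degenerate` with all indices 0.
The grouping search ranks candidate partitions by F_CT descending then
F_SC ascending; exhaustive set-partition enumeration is offered up to 8
populations (Bell number growth makes larger searches explicit-list
only).

## Haplogroup resampling test

Observed counts per macro-haplogroup in a sample of size N are compared
with B = 100,000 multinomial draws of N haplotypes at user-supplied
reference frequencies (the published reference panel's frequencies are
not redistributable, so they are an input). The acceptance interval is
the smallest central interval holding ≥95 % of draws, ties broken toward
symmetric tail masses; with B = 10⁵ the interval can differ from the
exact binomial-marginal interval by one count at a boundary whose
coverage sits almost exactly at 0.95 (for example a marker at reference
frequency 0.2 in N = 27 has exact interval [2, 9] with mass 0.9508).
The two-sided p doubles the smaller empirical tail and caps at 1 —
symmetric and conservative. Haplogroups observed but absent from the
reference cannot be tested against a positive null and are floored at
p = 1/(B+1) with an `unreferenced` flag.

## Ordination

Classical scaling double-centers the squared distance matrix,
B = −½·J·D²·J, and eigendecomposes. Axes with non-positive eigenvalues
are dropped and their total magnitude reported; no Cailliez correction
is applied. For reproducible output the first nonzero loading of each
axis is made positive. Individual-level PCoA uses the allele-sharing
distance: per comparable locus 1 − (shared alleles)/2 with multiset
sharing in {0, 1, 2}, averaged over loci — the exact metric used by the
desktop PCoA tools is not specified anywhere, so this choice is labeled
in the output.

## Admixture post-processing

Component binning uses edges (0.20, 0.60): low = [0, 0.20],
mid = (0.20, 0.60), high = [0.60, 1]. Edges belong to the lower bin
except the high bin is closed at 0.60, honoring "more than 60 %" as the
operative threshold for synthetic-population membership while the
0–20/21–59/60–100 labels name the classes; proportions in (0.59, 0.60)
are mid. The synthetic population collects individuals at or above the
threshold along with their genotypes, ready for distance and ordination
stages.

The supervised ancestry estimator maximizes, per individual, the
likelihood of the mixture model P(allele) = Σₖ qₖ fₖ(allele) over the
simplex, by EM from a uniform start to relative log-likelihood change
< 1e-8 (≤ 2000 iterations) — deterministic, no MCMC. With identical
source profiles any q is ML and EM returns the uniform start. Alleles
absent from every source are smoothed with pseudo-frequency 1e-6.

Hardy-Weinberg: biallelic loci use the exact conditional test (summing
probabilities of heterozygote counts no more probable than observed,
given the allele counts); multi-allelic loci use a seeded Monte-Carlo
permutation of alleles among genotypes (B = 10,000) scored by the
conditional sample probability. Linkage disequilibrium uses a
permutation G-test on the genotype × genotype contingency table — the
same null as the classic likelihood-ratio EM test but exactly specified
and assumption-free. The fixed multiple-testing cutoff p < 1e-4 is kept
as configuration.

## Demography

The classic skyline converts each intercoalescent interval (i lineages,
length tᵢ, generations) into N̂ᵢ = tᵢ·i(i−1)/2 haploid effective
individuals; intervals tile [0, TMRCA] exactly. A generalized variant
pools adjacent intervals shorter than ε (default ε = 0). Full Bayesian
skyline inference over genealogy space is deliberately out of scope: the
demographic stage is exercised through simulation-recovery, where the
genealogy is known, which is the honest desk-scale counterpart of the
MCMC machinery.

Each per-interval estimate is exponentially distributed around the true
N, so single skylines are noisy by construction; summaries use
replicate medians evaluated on a time grid. The median trajectory
carries a roughly uniform multiplicative bias (length-biased interval
sampling), which cancels in ratio summaries such as the fractional
decline — this is why bottleneck depth is reported as
1 − N̂_min/N̂_plateau rather than in absolute individuals.

Calibration defaults: generation time 25 years (alternate 20–23-year
readings can be passed per analysis), mitochondrial clock
1.546 × 10⁻⁸ ± 3.675 × 10⁻⁹ substitutions/site/year (interpreted per
base pair; the per-generation rate is the annual rate × generation
time), Y-STR clock 8.2 × 10⁻⁴ ± 5.7 × 10⁻⁴ mutations/locus/generation,
and a node-calibration prior of mean 1411 generations (35,282 years at
25 years/generation), SD 100. `mean_rate_from_estimates` uses the
sample (n−1) standard deviation.

## Synthetic data

The coalescent simulator draws waiting times by time-rescaling through
piecewise epochs (constant or log-linear/exponential size), topology by
uniform pair merging. Haploid scaling applies throughout the uniparental
markers: E[T₂] = N generations. Sequences mutate under a finite-sites
model (Poisson(μLb) mutations per branch, uniform site, uniform
alternative base); at the default rates multiple hits are rare and
E[π·L] ≈ 2NμL. Y-STRs follow the stepwise mutation model —
Poisson(μb) steps of ±1 per branch and locus, floored at 1 repeat — so
two haplotypes separated T generations satisfy E[(X₁−X₂)²] = 2μT per
locus. Autosomal genotypes are drawn from K-component mixtures of
allele-frequency profiles, not from a coalescent, since no autosomal
sequence-level analysis is in scope.

The packaged scenario generates four populations. The female history
grows from N = 200 (ancient) to a plateau of N = 2000 between 625 and
250 generations ago and declines from 125 generations ago to 40 % of
the plateau at present, with no rebound. The male history shares the
ancient shape but declines steeply to 50 % of the plateau at 25
generations ago and rebounds 20 % toward the present. Plateau size and
sample sizes (~60 haploid samples per sex-specific analysis) are the
package's own choices for statistical power; the source study's absolute
Ne axes are not published. Autosomal loci emulate the forensic panel's
composition (about 27 % six-allele STR-like loci, the rest biallelic),
with component profiles drawn from Dirichlet(0.5) — three components are
poorly identifiable from biallelic loci alone, and the multi-allelic
fraction is what carries most of the ancestry information. The third
ancestry component is concentrated in the Chachapoyas- and Jívaro-like
populations.

Within the Chachapoyas-like pool, subgroup labels are assigned
exchangeably over a single panmictic genealogy — the high-migration
limit of "migration keeps subgroups homogeneous". Consequently F_SC
among subgroups is non-significant in the expected ~95 % of replicates.
The main populations descend from separate genealogies (and, for
Y-STRs, distinct founder repeat counts), which produces strong
between-population differentiation — stronger than real populations
exhibit. The generator therefore supports calibration and recovery
testing, not effect-size realism: passing tests show the estimators are
correct and calibrated under known truth, not that real data would
yield any particular Φ_ST magnitude. It also omits recombination,
selection, finite-migration island structure, and sequencing error.

## Numerical conventions

- Seeds are mandatory arguments of every stochastic routine and are
  recorded in outputs; all simulators are bit-reproducible per seed.
- Permutation p-values use (b+1)/(B+1); statistic comparisons include a
  1e-12 slack so exact ties count as "as extreme".
- Negative MDS eigenvalues are dropped (magnitude reported); negative
  variance components and Φ_ST estimates are reported as computed.
- Problem sizes used by the verification suites (500 null simulations at
  n = 16 with 200 permutations; 200 skyline replicates of 60 tips; 200
  individuals at 100 loci for ancestry recovery; 2000 pairwise-TMRCA
  draws) were chosen so each suite completes in seconds while leaving
  Monte-Carlo error well below the tolerances asserted.

## Limitations

- Haplogroup calling from sequence (Phylotree logic) is out of scope;
  haplogroup labels are consumed as input, as are Q matrices from
  clustering software.
- The supervised ancestry estimator is a testable stand-in for
  unsupervised admixture MCMC: it requires source allele-frequency
  profiles and cannot discover components.
- Reference panels (e.g. the Peruvian haplogroup frequencies, N = 442)
  are not redistributable and must be supplied by the user; published
  AMOVA/Φ_ST values that depend on merged third-party genotype panels
  are not reproducible from this package alone.
- The classic skyline is a noisy estimator; single-genealogy
  trajectories should not be over-interpreted, and absolute N̂ levels
  carry bias that only cancels in ratios.
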