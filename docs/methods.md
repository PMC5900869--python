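# Methods

`radintro` implements the statistical machinery for measuring historical
and contemporary gene flow between a pair of hybridizing sister plant taxa
with contrasting mating systems — an outcrosser (referred to throughout as
*rivale*, F_IS ≈ 0.25) and a selfer (*urbanum*, F_IS ≈ 0.95) — genotyped
at 117-bp ddRAD tags mapped to a draft genome of the selfing species.
This note records the models, conventions and numerical choices.

## Blockwise site-frequency-spectrum likelihood

### Data and site classes

The historical analysis uses a single diploid individual per species and
treats each radtag as one non-recombining, unlinked block. Within a block,
every variable site falls into one of four observable classes:

1. heterozygous in the rivale individual only (k₁),
2. heterozygous in the urbanum individual only (k₂),
3. heterozygous in both (k₃),
4. a fixed difference between two homozygous genotypes (k₄).

Sites at which both individuals are homozygous for the same allele are
invisible; sites with a missing or third-allele call in either individual
are excluded from the tally and counted in an exclusion report (the
original study does not state its convention; exclusion is this package's
choice). Blocks left with no variable site are dropped with a logged
count, because the tag assembler never reports monomorphic tags.

With unphased, unpolarized genotypes the class of a mutation depends only
on the *folded* composition (a, b) of the lineage carrying it, where a
and b count the sampled rivale and urbanum genomes it subtends:
(1,0)/(1,2) → class 1, (0,1)/(2,1) → class 2, (1,1) → class 3,
(2,0)/(0,2) → class 4, and (2,2) is invisible.

### Models and parameters

Three models of species divergence are compared:

* **div2** — an ancestral population splits instantaneously at time T into
  two descendants with no subsequent gene flow;
* **IM u→r** and **IM r→u** — the same history plus continuous
  unidirectional migration at scaled rate M.

Parameters (all dimensionless unless noted):

| parameter | meaning | default bounds (fit) |
|---|---|---|
| θ_anc | 4·N_anc·μ·ℓ, scaled mutation rate per ℓ-bp block; N_anc is constrained equal to N_rivale (the ancestor was almost certainly outcrossing) | 10⁻³ – 10 |
| ν | N_urbanum / N_anc (selfing is expected to reduce N_e) | 0.02 – 20 |
| T | split time in units of 2·N_anc generations | 0.02 – 20 |
| M | 4·N_anc·m migrants per generation (IM models only) | 10⁻⁴ – 10 |

Time runs backwards: coalescence occurs at rate 1 per lineage pair in the
rivale deme and the ancestor, 1/ν in the urbanum deme, and lineages
currently in the forward-time *recipient* deme migrate into the donor
deme at rate M/2 per lineage. Mutations fall on each lineage at rate θ/2
per unit time under an infinite-sites model within the block.

The fitting bounds above are deliberately narrower than the widest
defensible ranges: they still bracket every estimate plausible for
RAD-scale data by well over an order of magnitude, while keeping the
stiffest corner of the two-deme generator (tiny ν together with large T)
cheap to integrate. They are exposed as an option on `fit_model`.

### Exact configuration probabilities

P(k₁,k₂,k₃,k₄) is computed from a continuous-time Markov chain over the
ancestral lineage partitions of the four sampled genomes, each lineage
tagged with its deme before T. Mutation counts are tracked on a truncated
grid: per class the categories are {0, 1, …, kmax_c, "> kmax_c"}, default
kmax = (4,4,4,4). The tail category *absorbs* further mutations of that
class inside the generator, so a single computation yields the complete
lumped distribution, exactly summing to one, with every interior cell
carrying the exact probability of that configuration. (An equivalent
construction via marginal subtraction would need one run per marginal;
the absorbing-tail form is one pass.)

Numerically, the finite-horizon phase [0, T] is propagated by
uniformization with the Poisson series truncated at mass 10⁻¹⁴ per step
(steps sized so λ·Δt ≤ 30), and the panmictic absorbing phase after T is
solved exactly, layer by layer in total mutation count, by small dense
linear solves (one matrix inverse per tail pattern). Both stages are far
inside the 10⁻⁶ relative-accuracy contract; the engine is validated
against two independent Monte-Carlo simulators (below). A full table at
the default truncation costs ~5 ms (div2) to ~13 ms (IM) on one core.

### Likelihood, fitting, intervals

Because monomorphic blocks are unobservable, the likelihood is
conditioned on variability:

  ln L = Σ_b ln P(k_b) − B · ln(1 − p_IBS),

where p_IBS = P(0,0,0,0) and counts beyond the truncation are lumped into
the tail categories. Maximization is by Nelder–Mead on log₁₀-transformed
parameters within bounds, restarted from seeded Latin-hypercube points
(default 5 restarts). 95% intervals for any parameter come from the
discretized profile (marginal support) curve with the standard 1.92
log-unit drop (χ²₁/2); because linear interpolation of the crossing on a
coarse log grid is biased toward the MLE (we measured profile intervals
up to ~30% too narrow, dropping coverage to 15/20), the threshold
crossings are located by bisection with the true profiled objective to a
log-spacing of 0.01. Model comparison reports Δln L relative to the best
model and flags models more than 2 log-units worse.

Natural-unit conversions use N = θ_site/(4μ) with μ = 7×10⁻⁹ per site per
generation and a 3-year generation time: t_years = T·2N_anc·g. M itself
is read as migrants per generation, so 1/M is the expected number of
generations between effective migrants (M = 0.04 → one migrant every 25
generations).

Known model limitations: constant N_e within each branch; no
recombination within blocks and free recombination between them; a single
diploid pair, so inbreeding in the sampled individuals depresses
within-species heterozygosity classes; and a neutral-mutation assumption
that in practice under-predicts the proportion of monomorphic blocks (no
correction is applied).

## Monte-Carlo simulators

`simulate_im_blocks` is a vectorized Gillespie simulation of the same
4-lineage structured coalescent (per-class branch lengths accumulated
event by event, Poisson mutations dropped at rate θ/2), simulating 10⁶
blocks in a few seconds; it is the brute-force oracle for the analytic
engine. `simulate_im_blocks_msprime` implements the identical contract on
msprime (population sizes 0.5 and ν/2 so one msprime generation equals
2·N_anc generations) and is cross-checked against the Gillespie simulator
under asymmetric migration, which also pins down the migration-rate
orientation. Oracle-equivalence testing compares, at 10⁶ blocks per
parameter set, each per-class marginal mean and the monomorphic
probability at 3 Monte-Carlo SE, plus a Pearson chi-square consistency
test on the full joint category grid with cells pooled below an expected
count of 5; per-cell 3-SE assertions over hundreds of multinomial cells
would reject a correct implementation with high probability by chance
alone, so the per-cell form is deliberately not used.

## Summary statistics

* **Per-SNP statistics** — allele frequencies use called alleles only (no
  imputation). Ho = heterozygotes / called; He = 2p(1−p); F_IS = 1 −
  Ho/He, undefined (NaN) where He = 0. No small-sample correction is
  applied to either quantity.
* **Paralog filter** — a scaffold is excluded if *any* of its SNPs, in
  *either* species (computed on the allopatric samples), shows Ho
  strictly above 0.5 or F_IS strictly below 0; Ho = 0.5 with F_IS = 0 is
  retained. Pooled reads from duplicated regions masquerade as
  heterozygotes, and population structure only depresses heterozygosity,
  so excess heterozygosity is a one-sided paralogy signal. At realistic
  sample sizes (10–14 individuals) the strict F_IS < 0 rule necessarily
  also removes a substantial fraction of clean scaffolds by sampling
  noise; this is inherent to the filter, not an artefact of this
  implementation.
* **F_ST** — Hudson's estimator, ratio of averages across loci, pairwise
  between populations. (The original pipeline's estimator is not fully
  specified; properties, not printed values, are the contract here.)
* **dxy** — per scaffold, Σ over qualifying SNPs of PX(1−PY) + (1−PX)PY
  divided by the number of genotyped sites on the scaffold's analysed
  radtags (SNPs must be called in ≥ 12 individuals per group by default);
  the mean and SE are taken across scaffolds. Because monomorphic radtags
  never enter the denominator, dxy here is a *relative* measure — valid
  for allopatric-vs-sympatric contrasts, not as absolute divergence.
* **f3** — the raw mean over SNPs of (c−a)(c−b) for target c and sources
  a and b, exactly as used in the study; no heterozygosity bias
  correction or normalization is applied. The 95% CI resamples whole
  scaffolds with replacement (2,000 replicates, percentile interval);
  "significant introgression" requires the CI entirely below zero. Note
  the statistic's null behaviour: measurement noise in c biases f3
  *positive*, so only significantly negative values are evidence of
  admixture.
* **Composition test** — Pearson chi-square comparing a SNP subset's
  category mix against the full classification, with a Monte-Carlo null
  (multinomial simulation) whenever an expected count falls below 5. No
  multiple-testing correction is applied anywhere in the package.

## Diagnostic panels, hybrid index, co-segregation

The panel is built from SNPs alternately fixed between allopatric
training samples; the primary panel keeps the *first* (lowest 1-based
position) such SNP per scaffold to limit linkage, which biases against
long, well-assembled scaffolds; all alternately fixed SNPs are retained
as a secondary panel. Validation removes a panel SNP when any holdout
individual of known species is homozygous for the other species' allele
(heterozygous holdouts are not removal evidence — they could be genuine
admixture); removed SNPs are logged, not replaced.

The hybrid index of an individual is HI = (2·hom_r + het)/(2n) over its
scorable panel loci (missing and third-allele calls excluded, index
renormalized). Class calls are strict: HI > 0.97 → rivale, HI < 0.03 →
urbanum, otherwise hybrid; an F1 sits at 0.5, a selfed F1 near 0.5 with
~25/50/25 genotype proportions, a first-generation backcross to rivale
near 0.75 with no homozygous-urbanum genotype at truly fixed loci.

Pure-classed individuals carrying opposite-species alleles at panel loci
are introgression candidates. Candidate loci whose genotype-state vectors
agree at every co-called recipient and share at least one carrier are
grouped (union–find), and a group is reported when it spans ≥ 2 scaffolds
with ≥ 3 carrier individuals; comparing only co-called entries keeps a
genuine un-recombined block intact when stray missing calls differ
between its loci. Each group is augmented with secondary-panel SNPs on
member scaffolds showing the same complete association; locus pairs with
shared carriers but mismatching states are reported as partial
associations with a mismatch count.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, on
scaffold-structured 117-bp radtags: per-SNP true categories drawn from
the observed mix (22.2% alternately fixed, 60.8% polymorphic in rivale
only, 15.4% in urbanum only, 1.5% shared); within-species allele
frequencies from a symmetric Beta(0.5, 0.5) (the U-shaped spectrum; the
real spectrum is unknown, so this is a modelling choice, exposed in
`SimSpec`); genotypes drawn under inbreeding F per species (p²+Fpq,
2pq(1−F), q²+Fpq; defaults 0.25 / 0.95); Balding–Nichols
among-population structure for allopatric samples (defaults F_ST 0.13 /
0.38); paralog scaffolds (default 4%, matching 1,344/32,182) whose SNPs
are forced heterozygous with high probability in every individual;
hybrids built by explicit Mendelian gamete sampling (F1, selfed F1,
backcross to rivale, selfed backcross); missing genotypes
missing-completely-at-random (default 5%); and optionally a planted
introgressed haplotype — the donor allele written, hom or het, at every
truly alternately-fixed SNP on a small set of scaffolds chosen so that
each scaffold's first SNP is truly diagnostic (otherwise the
one-SNP-per-scaffold panel could not tag the block, and no scan of panel
loci could ever find it). All latent labels are returned as ground truth.

Default dimensions follow the study: ~500 scaffolds at ~1.32 radtags
each (~660 blocks), ~2.1 SNPs per radtag, 14 + 22 allopatric and 46 + 46
sympatric individuals plus 4 planted hybrids.

What the generator does *not* emulate: read-level error and coverage (no
FASTQ, no genotype-likelihood noise), linkage disequilibrium within
scaffolds for the genotype matrix (SNP categories and frequencies are
drawn independently; only the planted haplotype is correlated), the
hexaploid ancestry of the genomes (paralogy appears solely as the
artefact class the filter targets), and informative missingness. Passing
tests therefore demonstrate the correctness of the statistical machinery
under the assumed model, not robustness to assembly or genotyping
pathologies in real ddRAD data.

"Noise-free" fixtures used by the exact-recovery tests set the missing
rate to zero and the paralog artefact probability to one; where a check
requires per-SNP heterozygosity itself to be noiseless (exact paralog
recovery), both species are additionally made fully selfing so every
clean SNP has Ho = 0 — with moderate inbreeding and 10–14 samples the
strict filter unavoidably excludes clean scaffolds by chance, which is
the realistic regime, not an error.

## Problem sizes in tests and the acceptance script

Oracle equivalence runs 10⁶ blocks at three parameter sets (no
migration, u→r, r→u). Parameter recovery runs 20 replicates of 660
variable blocks at study-vicinity truth (N_anc = 1.3×10⁵ scaled to θ per
block, ν = 0.29, T from a 2.2-Myr split) with 3 optimizer restarts per
fit and a 9-point profile grid for T. f3 calibration uses 500 scaffolds
× 3 SNPs with 2,000 bootstrap replicates, 20 replicates. The acceptance
script repeats the same computations at single-replicate scale (2×10⁵
oracle blocks) so a full run takes well under a minute.
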