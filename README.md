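# radintro

Introgression analysis for ddRAD data from a pair of hybridizing sister
plant taxa with contrasting mating systems — an outcrosser ("rivale",
F_IS ≈ 0.25) and a habitual selfer ("urbanum", F_IS ≈ 0.95). The package
is aimed at population geneticists who want to quantify both *historical*
gene flow (from a coalescent model of a single diploid pair) and
*contemporary* introgression (from panels of species-diagnostic SNPs in
sympatric samples), starting from a VCF of stacks-style radtag genotypes.

## What it computes

**Blockwise-SFS coalescent model comparison.** For one diploid per
species, each 117-bp radtag is an unlinked block carrying counts
(k₁, k₂, k₃, k₄) of four site classes: heterozygous in rivale only, in
urbanum only, in both, or a fixed difference. The package computes the
exact probability of every block configuration under three models —
strict divergence (div2: θ_anc, ν = N_urb/N_anc, T) and
isolation-with-migration in either direction (+ M = 4N_anc·m) — by a
continuous-time Markov chain over ancestral lineage partitions, and
maximizes the likelihood conditioned on variable blocks:

    ln L = Σ_b ln P(k_b) − B · ln(1 − p_IBS)

with profile-likelihood 95% support intervals (1.92 log-unit drop) and
Δln L model comparison (< −2 ⇒ significantly worse). Estimates convert
to natural units via N = θ/(4μ), t = T·2N·g (defaults μ = 7×10⁻⁹,
g = 3 yr); M is migrants per generation, so M = 0.04 is one migrant
every 25 generations.

**Summary statistics.** Polymorphism-type classification of SNPs within
and between species, per-SNP Ho / He / F_IS, a paralog scaffold filter
(exclude scaffolds with any SNP of Ho > 0.5 or F_IS < 0 — the signature
of co-mapped duplicated regions), Hudson F_ST, per-scaffold dxy with
mean ± SE across scaffolds, the f3 admixture test (mean of (c−a)(c−b);
2,000-scaffold bootstrap CI; significantly negative ⇒ admixture in c),
and a chi-square composition test.

**Hybrid and introgression scans.** Species-diagnostic panels built from
alternately fixed SNPs in allopatric samples (first SNP per scaffold),
validated on holdout individuals; per-individual hybrid indices
HI = (2·hom_r + het)/(2n) with the > 97% classification rule; lists of
opposite-species alleles carried by pure individuals; and a scan for
co-segregating putatively introgressed blocks spanning multiple
scaffolds (complete genotypic association across carriers).

**Synthetic data.** A generator that emulates the whole data structure —
scaffold-structured radtags, the observed SNP category mix, contrasting
inbreeding, population structure, paralog artefacts, Mendelian hybrids,
a plantable introgressed haplotype, missing data — with full ground
truth, so every stage is testable without any download; plus structured-
coalescent block simulators (vectorized Gillespie, and msprime as an
independent cross-check) that serve as the Monte-Carlo oracle for the
likelihood engine.

## Worked example

Simulate 660 variable blocks for a diploid pair under strict divergence
at study-like values (θ per block 0.426 ⇒ N_anc ≈ 1.3×10⁵, ν = 0.29,
T = 2.82 ⇒ a split ~2.2 Myr ago), then fit and compare all three models:

```python
from radintro import (IMParams, BsfsData, fit_model, compare_models,
                      to_natural_units, simulate_im_block_counts)

truth = IMParams(theta_anc=0.426, nu=0.29, T=2.82, M=0.0, direction="none")
counts = simulate_im_block_counts(truth, 1000, seed=11)
data = BsfsData(counts[counts.sum(axis=1) > 0][:660])
fits = [fit_model(data, m, seed=0, n_restarts=3)
        for m in ("div2", "IM_u_to_r", "IM_r_to_u")]
for row in compare_models(fits):
    print(f"{row['model']:10s} delta lnL = {row['delta_lnL']:.3f}")
units = to_natural_units(fits[0])
print(f"N_anc = {units.N_anc:.3g}, N_urb = {units.N_urb:.3g}, "
      f"t = {units.t_years:.3g} years")
```

prints

```
div2       delta lnL = -0.063
IM_u_to_r  delta lnL = -0.069
IM_r_to_u  delta lnL = 0.000
N_anc = 1.36e+05, N_urb = 4.45e+04, t = 2.21e+06 years
```

All three models fit this migration-free data equally well (no Δln L
below −2, so nothing is rejected; the IM fits drive M to the boundary),
and the strict-divergence estimates recover the simulated truth:
ancestral/rivale N_e ≈ 1.4×10⁵, a four-fold smaller N_e in the selfer,
and a split ≈ 2.2 Myr ago.

## The analysis pipeline

The numbered scripts under `analysis/` run the full study workflow on a
synthetic study-scale dataset (~500 scaffolds, 36 allopatric + 96
sympatric samples including 4 planted hybrids and one planted
two-scaffold introgressed haplotype), writing tables under `results/`:

```bash
python analysis/01_simulate_dataset.py        # fixture + ground truth
python analysis/02_filter_and_classify.py     # paralog filter, SNP classes
python analysis/03_hybrids_and_introgression.py
python analysis/04_divergence_and_f3.py       # dxy, F_ST, f3
python analysis/05_coalescent_model_fit.py    # bSFS model comparison
```

Script 03, for example, flags exactly the four planted hybrids (hybrid
indices 46.5%, 49.7%, 73.6%, 71.2%) and finds the planted introgressed
block as a single complete co-segregation group with 7 carriers; script
04 shows dxy is the same in allopatry and sympatry and both f3 CIs
contain zero — the no-contemporary-introgression picture the hybrid scan
then qualifies.

The same steps are available as a CLI (`radintro simulate | make-fixture
| filter-paralogs | classify-sites | fst | dxy | f3 | panel |
hybrid-index | introgression-scan | bsfs-tally | bsfs-fit | run`), with
`radintro run --config cfg.yaml` chaining them from a single YAML file.

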