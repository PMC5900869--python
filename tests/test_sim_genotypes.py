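"""Genotype-matrix generator: Mendelian crosses, inbreeding, planted
artefacts and ground-truth bookkeeping."""

import numpy as np
import pytest

from radintro.genotypes import MISSING
from radintro.sim.genotypes import (SimSpec, IntrogressionPlan, cross,
                                    simulate_genotype_dataset)
from radintro.summary_stats import snp_stats


def small_spec(**kw):
    base = dict(n_scaffolds=60, radtags_per_scaffold=1.0,
                mean_snps_per_radtag=3.0, n_allopatric_r=12,
                n_allopatric_u=12, n_sympatric_r=10, n_sympatric_u=10,
                paralog_scaffold_frac=0.0, missing_rate=0.0)
    base.update(kw)
    return SimSpec(**base)


def test_reproducible_bit_for_bit():
    spec = small_spec(missing_rate=0.1,
                      hybrid_pedigrees=(("F1", 1),))
    m1, t1 = simulate_genotype_dataset(spec, seed=5)
    m2, t2 = simulate_genotype_dataset(spec, seed=5)
    np.testing.assert_array_equal(m1.genotypes, m2.genotypes)
    assert t1.snps.equals(t2.snps)
    assert t1.samples.equals(t2.samples)


def test_spec_validation():
    with pytest.raises(ValueError):
        small_spec(frac_alt_fixed=0.8, frac_poly_r=0.5).validate()
    with pytest.raises(ValueError):
        small_spec(missing_rate=1.5).validate()
    with pytest.raises(ValueError):
        small_spec(frac_alt_fixed=0.0, frac_poly_r=0.9,
                   hybrid_pedigrees=(("F1", 1),)).validate()
    with pytest.raises(ValueError):
        small_spec(hybrid_pedigrees=(("F3", 1),)).validate()


def test_truth_labels_partition():
    spec = small_spec(paralog_scaffold_frac=0.1,
                      hybrid_pedigrees=(("F1", 1), ("BC1_r", 2)))
    m, truth = simulate_genotype_dataset(spec, seed=9)
    assert len(truth.samples) == m.n_samples
    assert truth.samples["sample_id"].is_unique
    assert truth.scaffolds["scaffold"].is_unique
    assert len(truth.hybrids()) == 3


def test_f1_heterozygous_at_every_fixed_difference():
    """An F1 with complete data is het wherever the species are truly
    alternately fixed, so its hybrid index is exactly 0.5 there."""
    spec = small_spec(hybrid_pedigrees=(("F1", 2),))
    m, truth = simulate_genotype_dataset(spec, seed=3)
    fixed = truth.snps["category"].to_numpy() == "alternately_fixed"
    assert fixed.sum() > 10
    for hyb in truth.hybrids():
        g = m.genotypes[m.sample_index(hyb)]
        assert (g[fixed] == 1).all()


def test_full_selfing_means_full_homozygosity():
    spec = small_spec(selfing_F_u=1.0)
    m, truth = simulate_genotype_dataset(spec, seed=8)
    urb = m.rows(m.group_ids(species="urbanum"))
    assert not (urb == 1).any()


def test_selfed_f1_segregation_ratios():
    """One selfing generation after an F1 gives 1:2:1 hom:het:hom at
    truly fixed differences (within 3 binomial SE)."""
    spec = small_spec(n_scaffolds=300, mean_snps_per_radtag=2.0,
                      frac_alt_fixed=0.5, frac_poly_r=0.3,
                      frac_poly_u=0.15, frac_shared=0.05,
                      hybrid_pedigrees=(("F1_selfed", 1),))
    m, truth = simulate_genotype_dataset(spec, seed=17)
    fixed = truth.snps["category"].to_numpy() == "alternately_fixed"
    n = int(fixed.sum())
    assert n > 150
    g = m.genotypes[m.sample_index(truth.hybrids()[0])][fixed]
    het = (g == 1).mean()
    assert abs(het - 0.5) < 3 * np.sqrt(0.25 / n)
    for hom in ((g == 0).mean(), (g == 2).mean()):
        assert abs(hom - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)


def test_cross_basic_rules():
    rng_seed = 23
    a = np.zeros(50, dtype=np.int8)        # hom ref
    b = np.full(50, 2, dtype=np.int8)      # hom alt
    f1 = cross(a, b, 0, seed=rng_seed)
    assert (f1 == 1).all()
    # backcross to the hom-ref parent can never be hom-alt
    bc = cross(f1, a, 0, seed=rng_seed)
    assert set(np.unique(bc)) <= {0, 1}
    # missing propagates
    a2 = a.copy()
    a2[0] = MISSING
    assert cross(a2, b, 0, seed=1)[0] == MISSING
    with pytest.raises(ValueError):
        cross(a, b[:10], 0)


def test_heterozygosity_halves_per_selfing_generation():
    n = 10_000
    a = np.zeros(n, dtype=np.int8)
    b = np.full(n, 2, dtype=np.int8)
    g10 = cross(a, b, selfing_generations=10, seed=2)
    het = (g10 == 1).mean()
    expected = 0.5 ** 10
    assert het <= expected + 3 * np.sqrt(expected / n)


def test_planted_paralogs_show_excess_heterozygosity():
    """Noise-free: every truth-flagged paralog scaffold has at least one
    SNP with observed heterozygosity above 0.5."""
    spec = small_spec(paralog_scaffold_frac=0.2, artefact_het_prob=1.0)
    m, truth = simulate_genotype_dataset(spec, seed=6)
    stats = snp_stats(m, m.group_ids(species="rivale"))
    flagged = truth.paralog_scaffolds & set(m.scaffold)
    for scaf in flagged:
        sub = stats[stats["scaffold"] == scaf]
        assert (sub["Ho"] > 0.5).any()


def test_introgression_plant_respects_truth():
    spec = small_spec(n_sympatric_u=20,
                      introgressed_block=IntrogressionPlan(
                          n_scaffolds=2, n_hom_carriers=3,
                          n_het_carriers=1))
    m, truth = simulate_genotype_dataset(spec, seed=12)
    assert len(truth.introgressed_scaffolds) == 2
    assert len(truth.introgression_carriers) == 4
    states = truth.introgression_carriers["state"].value_counts()
    assert states["hom"] == 3 and states["het"] == 1
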