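"""Summary statistics: polymorphism classes, heterozygosity, paralog
filter, F_ST, dxy, f3 and the composition test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_matrix
from radintro import summary_stats as ss

SPECIES_4R_4U = ["rivale"] * 4 + ["urbanum"] * 4


def test_classification_examples():
    # columns: poly_r (r {A,T}, u {T}); alt fixed; monomorphic; shared
    g = [[1, 0, 0, 1],
         [0, 0, 0, 0],
         [1, 0, 0, 2],
         [0, 0, 0, 1],
         [2, 2, 0, 1],
         [2, 2, 0, 0],
         [2, 2, 0, 2],
         [2, 2, 0, 1]]
    m = make_matrix(g, species=SPECIES_4R_4U)
    table = ss.classify_polymorphism(m, [f"s{i}" for i in range(4)],
                                     [f"s{i}" for i in range(4, 8)])
    assert list(table.per_snp["category"]) == [
        "poly_r_only", "alternately_fixed", "monomorphic", "shared_poly"]
    assert table.counts["poly_r_only"] == 1
    assert table.total == 4


def test_classification_uncallable_group():
    g = [[1], [0], [-1], [-1]]
    m = make_matrix(g, species=["rivale", "rivale", "urbanum", "urbanum"])
    table = ss.classify_polymorphism(m, ["s0", "s1"], ["s2", "s3"])
    assert table.counts["uncallable"] == 1


@settings(max_examples=30, deadline=None)
@given(st.lists(st.integers(0, 2), min_size=8, max_size=8),
       st.permutations(range(8)))
def test_classification_invariances(column, perm):
    """Counts ignore individual ordering and allele-label swaps."""
    m1 = make_matrix(np.array(column)[:, None], species=SPECIES_4R_4U)
    r_ids = [f"s{i}" for i in range(4)]
    u_ids = [f"s{i}" for i in range(4, 8)]
    base = ss.classify_polymorphism(m1, r_ids, u_ids).counts
    # permute individuals within species
    perm_r = [p for p in perm if p < 4]
    perm_u = [p for p in perm if p >= 4]
    reordered = np.array(column)[perm_r + perm_u][:, None]
    m2 = make_matrix(reordered, species=SPECIES_4R_4U)
    assert ss.classify_polymorphism(m2, r_ids, u_ids).counts == base
    # swap allele labels (0 <-> 2)
    swapped = np.array([2 - c for c in column])[:, None]
    m3 = make_matrix(swapped, species=SPECIES_4R_4U)
    assert ss.classify_polymorphism(m3, r_ids, u_ids).counts == base


def test_snp_stats_hand_example():
    # genotypes AA, AA, AT, TT: p(A) = 0.625, Ho = 0.25, He = 0.46875
    m = make_matrix([[0], [0], [1], [2]], species=["rivale"] * 4)
    st_ = ss.snp_stats(m, [f"s{i}" for i in range(4)])
    assert st_["Ho"].iloc[0] == pytest.approx(0.25)
    assert st_["He"].iloc[0] == pytest.approx(0.46875)
    assert st_["F_IS"].iloc[0] == pytest.approx(0.4667, abs=5e-5)


def test_snp_stats_extremes():
    m = make_matrix([[1], [1], [1], [1]], species=["rivale"] * 4)
    st_ = ss.snp_stats(m, [f"s{i}" for i in range(4)])
    assert st_["F_IS"].iloc[0] == pytest.approx(-1.0)
    m2 = make_matrix([[0], [0], [2], [2]], species=["rivale"] * 4)
    st2 = ss.snp_stats(m2, [f"s{i}" for i in range(4)])
    assert st2["F_IS"].iloc[0] == pytest.approx(1.0)
    # monomorphic: He = 0 so F_IS undefined
    m3 = make_matrix([[0], [0], [0], [0]], species=["rivale"] * 4)
    assert np.isnan(ss.snp_stats(m3, [f"s{i}" for i in range(4)])
                    ["F_IS"].iloc[0])


def test_individual_pi():
    g = np.zeros((1, 10_000), dtype=np.int8)
    g[0, :9] = 1
    m = make_matrix(g, species=["rivale"])
    pi, se, n = ss.individual_pi(m, "s0")
    assert pi == pytest.approx(0.0009)
    assert n == 10_000


def test_paralog_filter_threshold_and_boundary():
    # SNP 1: Ho = 0.6 (3 het of 5) -> scaffold excluded
    # SNP 2 on another scaffold: Ho = 0.5 exactly, F_IS = 0 -> retained
    g_bad = [1, 1, 1, 0, 2]
    # p = 0.5, Ho = 0.5 -> F_IS = 0: genotypes 2 het, 1 hom-ref, 1 hom-alt
    g_edge = [1, 1, 0, 2, -1]
    m = make_matrix(np.array([g_bad, g_edge]).T,
                    species=["rivale"] * 5,
                    scaffold=["scA", "scB"], position=[1, 1])
    ids = [f"s{i}" for i in range(5)]
    retained, report = ss.paralog_filter(m, ids, ids, 0.5, 0.0)
    assert "scA" not in retained
    assert "scB" in retained
    # idempotent + partition
    excluded = set(report["scaffold"])
    assert retained | excluded == set(m.scaffold)


def test_paralog_filter_negative_fis_triggers():
    # excess het: 4 het of 4 -> F_IS = -1 < 0
    m = make_matrix([[1], [1], [1], [1]], species=["rivale"] * 4)
    retained, report = ss.paralog_filter(
        m, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4)])
    assert retained == set()


def test_fst_extremes_and_hand_value():
    # identical duplicated populations: F_ST ~ 0 (the unbiased estimator's
    # finite-sample correction leaves a small negative residual)
    n = 200
    col = ([0, 1, 2, 1] * (n // 4)) * 2
    m = make_matrix(np.array([col] * 5).T, species=["rivale"] * (2 * n))
    ids = [f"s{i}" for i in range(2 * n)]
    f = ss.fst(m, {"a": ids[:n], "b": ids[n:]})
    assert abs(f.loc["a", "b"]) < 0.01
    # alternately fixed at all loci -> 1
    ids8 = [f"s{i}" for i in range(8)]
    col2 = [0, 0, 0, 0, 2, 2, 2, 2]
    m2 = make_matrix(np.array([col2] * 5).T, species=["rivale"] * 8)
    f2 = ss.fst(m2, {"a": ids8[:4], "b": ids8[4:]})
    assert f2.loc["a", "b"] == pytest.approx(1.0)


def test_fst_matches_hudson_formula():
    # two pops of 50 diploids, p = 0.2 vs 0.8 exactly
    n = 50
    pop1 = [1] * 20 + [0] * 30          # 20 alt alleles / 100
    pop2 = [1] * 20 + [2] * 30          # 80 alt alleles / 100
    col = pop1 + pop2
    m = make_matrix(np.array([col]).T, species=["rivale"] * 100)
    ids = [f"s{i}" for i in range(100)]
    f = ss.fst(m, {"a": ids[:50], "b": ids[50:]})
    num = (0.6 ** 2) - 2 * (0.2 * 0.8 / 49)
    den = 0.2 * 0.2 + 0.8 * 0.8
    assert f.loc["a", "b"] == pytest.approx(num / den, rel=1e-12)


def test_dxy_examples_and_symmetry():
    ids_r = [f"s{i}" for i in range(4)]
    ids_u = [f"s{i}" for i in range(4, 8)]
    m = make_matrix([[2]] * 4 + [[0]] * 4, species=SPECIES_4R_4U)
    res = ss.dxy(m, ids_r, ids_u, {"sc1": 117}, min_called=4)
    assert res.mean == pytest.approx(1 / 117)
    res_swap = ss.dxy(m, ids_u, ids_r, {"sc1": 117}, min_called=4)
    assert res_swap.mean == res.mean
    # PX = 0.3, PY = 0.7 -> 0.58 / 117
    g_r = [[1], [1], [1], [0], [0]]          # 3/10 = 0.3
    g_u = [[1], [1], [1], [2], [2]]          # 7/10 = 0.7
    m3 = make_matrix(g_r + g_u, species=["rivale"] * 5 + ["urbanum"] * 5)
    res3 = ss.dxy(m3, [f"s{i}" for i in range(5)],
                  [f"s{i}" for i in range(5, 10)], {"sc1": 117},
                  min_called=5)
    assert res3.mean == pytest.approx(0.58 / 117)
    assert 0.0 <= res3.mean <= 1.0


def test_dxy_monomorphic_site_does_not_contribute():
    g_r = [[2, 2], [2, 2], [2, 2], [2, 2]]
    g_u = [[0, 2], [0, 2], [0, 2], [0, 2]]
    m = make_matrix(g_r + g_u, species=SPECIES_4R_4U,
                    scaffold=["sc1", "sc1"], position=[1, 2])
    res = ss.dxy(m, [f"s{i}" for i in range(4)],
                 [f"s{i}" for i in range(4, 8)], {"sc1": 117}, min_called=4)
    assert res.mean == pytest.approx(1 / 117)   # PX = PY = 1 adds nothing


def test_f3_arithmetic_and_degenerate_ci():
    # c equals source a termwise -> f3 = 0 with a degenerate CI
    a = np.array([0.2, 0.9, 0.4, 0.6])
    b = np.array([0.1, 0.5, 0.9, 0.2])
    scaf = np.array(["s1", "s1", "s2", "s2"])
    res = ss.f3_test(a, b, a, scaf, n_boot=200, seed=1)
    assert res.f3 == 0.0
    assert res.ci_lower == res.ci_upper == 0.0
    assert not res.significant_introgression
    # single-SNP arithmetic: (0.5-0.1)(0.5-0.9) = -0.16
    res2 = ss.f3_test([0.1, 0.1], [0.9, 0.9], [0.5, 0.5],
                      ["s1", "s2"], n_boot=100, seed=1)
    assert res2.f3 == pytest.approx(-0.16)


def test_f3_bootstrap_reproducible_and_scaling():
    rng = np.random.default_rng(0)
    n_scaf = 400
    p0 = rng.beta(0.5, 0.5, size=n_scaf * 3)
    scaf = np.repeat([f"sc{i}" for i in range(n_scaf)], 3)
    a = np.clip(p0 + rng.normal(0, 0.05, p0.size), 0, 1)
    b = np.clip(p0 + rng.normal(0, 0.05, p0.size), 0, 1)
    c = np.clip(p0 + rng.normal(0, 0.05, p0.size), 0, 1)
    r1 = ss.f3_test(a, b, c, scaf, n_boot=500, seed=9)
    r2 = ss.f3_test(a, b, c, scaf, n_boot=500, seed=9)
    np.testing.assert_array_equal(r1.bootstrap_values, r2.bootstrap_values)
    # CI width shrinks roughly like 1/sqrt(#scaffolds)
    half = ss.f3_test(a[:600], b[:600], c[:600], scaf[:600],
                      n_boot=500, seed=9)
    assert (r1.ci_upper - r1.ci_lower) < (half.ci_upper - half.ci_lower)


def test_f3_null_covers_zero():
    """Unadmixed target (a lightly drifted copy of one source, as when the
    target is the sympatric population of the same species): the bootstrap
    CI contains zero in >= 90% of replicates."""
    rng = np.random.default_rng(42)
    n_scaf, snps = 300, 3
    hits = 0
    for rep in range(20):
        a = rng.beta(0.5, 0.5, size=n_scaf * snps)
        b = rng.beta(0.5, 0.5, size=n_scaf * snps)
        scaf = np.repeat([f"sc{i}" for i in range(n_scaf)], snps)
        c = np.clip(a + rng.normal(0, 0.01, a.size), 0, 1)
        res = ss.f3_test(a, b, c, scaf, n_boot=300, seed=rep)
        if res.ci_lower <= 0.0 <= res.ci_upper:
            hits += 1
    assert hits >= 18


def test_f3_requires_two_scaffolds():
    with pytest.raises(ValueError):
        ss.f3_test([0.1], [0.2], [0.3], ["s1"], n_boot=10, seed=0)


def test_composition_test_contract():
    total = ss.PolymorphismTable.from_counts(
        {"alternately_fixed": 488, "poly_r_only": 1334,
         "poly_u_only": 338, "shared_poly": 34})
    same = ss.composition_test(total, total)
    assert same["statistic"] == pytest.approx(0.0)
    assert same["p_value"] > 0.99
    skewed = ss.PolymorphismTable.from_counts(
        {"alternately_fixed": 100, "poly_r_only": 0,
         "poly_u_only": 0, "shared_poly": 0})
    res = ss.composition_test(skewed, total)
    assert res["p_value"] < 0.001
    with pytest.raises(ValueError):
        ss.composition_test(ss.PolymorphismTable.from_counts(
            {"alternately_fixed": 0}), total)


def test_composition_test_null_is_calibrated():
    """Proportional subsets give non-extreme p-values under the null."""
    rng = np.random.default_rng(3)
    total = ss.PolymorphismTable.from_counts(
        {"alternately_fixed": 488, "poly_r_only": 1334,
         "poly_u_only": 338, "shared_poly": 34})
    p_exp = np.array([488, 1334, 338, 34]) / 2194
    low = 0
    for rep in range(40):
        draw = rng.multinomial(60, p_exp)
        sub = ss.PolymorphismTable.from_counts(dict(zip(
            ("alternately_fixed", "poly_r_only", "poly_u_only",
             "shared_poly"), draw.tolist())))
        res = ss.composition_test(sub, total, seed=rep)
        if res["p_value"] < 0.05:
            low += 1
    assert low <= 6   # ~5% expected under the null
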