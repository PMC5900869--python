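"""Diagnostic panels, hybrid indices, class calls and co-segregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_matrix
from radintro import hybrid as hy

R4U4 = ["rivale"] * 4 + ["urbanum"] * 4
R_IDS = [f"s{i}" for i in range(4)]
U_IDS = [f"s{i}" for i in range(4, 8)]


def test_build_panel_takes_first_snp_per_scaffold():
    g = np.zeros((8, 3), dtype=np.int8)
    g[:4] = 2  # all three alternately fixed
    m = make_matrix(g, species=R4U4,
                    scaffold=["scA", "scA", "scB"],
                    position=[90, 50, 10])
    panel = hy.build_panel(m, R_IDS, U_IDS)
    assert len(panel.secondary) == 3
    assert panel.n_snps == 2
    got = dict(zip(panel.primary["scaffold"], panel.primary["position"]))
    assert got == {"scA": 50, "scB": 10}


def test_build_panel_excludes_polymorphic_training_sites():
    # column 0 fixed; column 1 fixed in rivale but polymorphic in urbanum
    g = np.array([[2, 2]] * 4 + [[0, 0], [0, 0], [0, 1], [0, 0]],
                 dtype=np.int8)
    m = make_matrix(g, species=R4U4, scaffold=["scA", "scB"],
                    position=[1, 1])
    panel = hy.build_panel(m, R_IDS, U_IDS)
    assert list(panel.primary["scaffold"]) == ["scA"]


def test_build_panel_empty_warns():
    g = np.zeros((8, 1), dtype=np.int8)
    m = make_matrix(g, species=R4U4)
    with pytest.warns(UserWarning):
        panel = hy.build_panel(m, R_IDS, U_IDS)
    assert panel.n_snps == 0


def test_validate_panel_rules():
    # three fixed SNPs; one extra 'urbanum' holdout individual that is
    # hom-rivale at SNP 1 and het at SNP 0
    g = np.zeros((9, 3), dtype=np.int8)
    g[:4] = 2
    g[8] = [1, 2, 0]
    m = make_matrix(g, species=R4U4 + ["urbanum"],
                    scaffold=["scA", "scB", "scC"], position=[1, 1, 1])
    panel = hy.build_panel(m, R_IDS, U_IDS)
    assert panel.n_snps == 3
    pruned = hy.validate_panel(panel, m, ["s8"], "urbanum")
    assert pruned.n_snps == 2
    assert list(pruned.validation_log["scaffold"]) == ["scB"]
    # heterozygous holdout does not trigger removal
    assert "scA" in set(pruned.primary["scaffold"])


def test_validate_panel_guards():
    g = np.zeros((8, 1), dtype=np.int8)
    g[:4] = 2
    m = make_matrix(g, species=R4U4)
    panel = hy.build_panel(m, R_IDS, U_IDS)
    with pytest.raises(ValueError):
        hy.validate_panel(panel, m, [U_IDS[0]], "urbanum")
    with pytest.warns(UserWarning):
        same = hy.validate_panel(panel, m, [], "urbanum")
    assert same.n_snps == panel.n_snps


def test_validation_idempotent_on_clean_training_data():
    g = np.zeros((8, 4), dtype=np.int8)
    g[:4] = 2
    m = make_matrix(g, species=R4U4,
                    scaffold=[f"sc{j}" for j in range(4)],
                    position=[1] * 4)
    panel = hy.build_panel(m, R_IDS[:3], U_IDS[:3])
    pruned = hy.validate_panel(panel, m, [R_IDS[3]], "rivale")
    assert pruned.n_snps == panel.n_snps


def test_hybrid_index_worked_tabulations():
    """Genotype-class counts map onto the published index arithmetic."""
    cases = [(9, 166, 20, 47.2), (7, 132, 22, 45.3),
             (138, 28, 7, 87.9), (95, 113, 6, 70.8)]
    for hom_r, het, hom_u, expected in cases:
        r = hy.HybridIndexResult("x", hom_r, het, hom_u)
        assert r.n_loci == hom_r + het + hom_u
        assert r.percent_rivale == expected


def test_hybrid_index_from_genotypes_and_exclusions():
    g = np.zeros((9, 4), dtype=np.int8)
    g[:4] = 2
    g[8] = [1, 1, 1, -1]   # het at three loci, one missing
    m = make_matrix(g, species=R4U4 + ["urbanum"],
                    scaffold=[f"sc{j}" for j in range(4)], position=[1] * 4)
    panel = hy.build_panel(m, R_IDS, U_IDS)
    r = hy.hybrid_index(m, "s8", panel)
    assert (r.hom_r, r.het, r.hom_u, r.n_excluded) == (0, 3, 0, 1)
    assert r.hybrid_index == 0.5


def test_classification_thresholds():
    mk = lambda hr, het, hu: hy.HybridIndexResult("x", hr, het, hu)
    assert hy.classify_individual(mk(100, 0, 0)) == "rivale"
    assert hy.classify_individual(mk(0, 0, 100)) == "urbanum"
    assert hy.classify_individual(mk(9, 166, 20)) == "hybrid"
    # HI exactly at the threshold stays 'hybrid' (strict inequality)
    assert hy.classify_individual(mk(97, 0, 3), 0.97) == "hybrid"
    with pytest.raises(ValueError):
        hy.classify_individual(mk(0, 0, 0))


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200))
def test_classification_partitions_unit_interval(hr, het, hu):
    if hr + het + hu == 0:
        return
    r = hy.HybridIndexResult("x", hr, het, hu)
    assert 0.0 <= r.hybrid_index <= 1.0
    assert hy.classify_individual(r) in {"rivale", "urbanum", "hybrid"}


def _introgression_fixture(n_recipients=45, hom=6, het=1, missing=()):
    """Pure rivale/urbanum groups + a planted donor haplotype on two
    scaffolds in some urbanum individuals."""
    n = 4 + n_recipients
    cols = 4   # scaffolds scA..scD, one diagnostic SNP each
    g = np.zeros((n, cols), dtype=np.int8)
    g[:4] = 2  # rivale training: hom alt everywhere
    # urbanum recipients: hom ref; planted block on scA+scB
    for i in range(hom):
        g[4 + i, 0] = g[4 + i, 1] = 2
    for i in range(hom, hom + het):
        g[4 + i, 0] = g[4 + i, 1] = 1
    for (row, col) in missing:
        g[row, col] = -1
    species = ["rivale"] * 4 + ["urbanum"] * n_recipients
    m = make_matrix(g, species=species,
                    scaffold=["scA", "scB", "scC", "scD"],
                    position=[1] * cols)
    panel = hy.build_panel(m, [f"s{i}" for i in range(4)],
                           [f"s{i}" for i in range(4 + hom + het, n)])
    classes = {f"s{i}": "urbanum" for i in range(4, n)}
    return m, panel, classes


def test_candidate_allele_counting():
    m, panel, classes = _introgression_fixture()
    cand = hy.introgression_candidates(m, panel, classes)
    # 6 hom + 1 het carriers = 13 alleles among 45 diploids
    locus = cand.per_locus[cand.per_locus["scaffold"] == "scA"].iloc[0]
    assert locus["carrier_freq"] == pytest.approx(13 / 90)
    assert locus["n_carriers"] == 7
    s4 = cand.per_individual[cand.per_individual["sample_id"] == "s4"]
    assert s4["n_opposite_alleles"].sum() == 4  # hom at two loci


def test_candidates_empty_when_no_opposite_alleles():
    m, panel, classes = _introgression_fixture(hom=0, het=0)
    cand = hy.introgression_candidates(m, panel, classes)
    assert len(cand.per_locus) == 0


def test_cosegregation_finds_planted_block():
    m, panel, classes = _introgression_fixture()
    cand = hy.introgression_candidates(m, panel, classes)
    scan = hy.cosegregation_scan(cand, m, panel, classes)
    assert len(scan) == 1
    group = scan[0]
    assert group.scaffolds == {"scA", "scB"}
    assert group.n_carriers == 7
    assert sorted(group.carriers["state"]) == ["het"] + ["hom"] * 6
    # completeness invariant: identical states across carriers re-checked
    rows = m.rows(group.carriers["sample_id"])
    cols = [int(np.flatnonzero((m.scaffold == s) & (m.position == p))[0])
            for s, p in group.loci]
    assert (rows[:, cols[0]] == rows[:, cols[1]]).all()


def test_cosegregation_min_carriers_rule():
    m, panel, classes = _introgression_fixture(hom=1, het=1)
    cand = hy.introgression_candidates(m, panel, classes)
    scan = hy.cosegregation_scan(cand, m, panel, classes, min_carriers=3)
    assert len(scan) == 0


def test_cosegregation_null_rarely_groups():
    """Independent rare opposite alleles almost never form a complete
    two-scaffold group with >= 3 carriers."""
    rng = np.random.default_rng(77)
    n_found = 0
    reps = 100
    for _ in range(reps):
        n_rec, cols = 45, 6
        g = np.zeros((4 + n_rec, cols), dtype=np.int8)
        g[:4] = 2
        carry = rng.random((n_rec, cols)) < 0.05
        g[4:][carry] = 1
        m = make_matrix(g, species=["rivale"] * 4 + ["urbanum"] * n_rec,
                        scaffold=[f"sc{j}" for j in range(cols)],
                        position=[1] * cols)
        clean = [f"s{i + 4}" for i in range(n_rec)
                 if not carry[i].any()][:5]
        assert clean, "null fixture needs at least one clean trainer"
        panel = hy.build_panel(m, [f"s{i}" for i in range(4)], clean)
        classes = {f"s{i}": "urbanum" for i in range(4, 4 + n_rec)}
        cand = hy.introgression_candidates(m, panel, classes)
        scan = hy.cosegregation_scan(cand, m, panel, classes)
        if len(scan):
            n_found += 1
    assert n_found <= 5
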