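"""Analytic blockwise configuration probabilities: limits, symmetries and
agreement with the Monte-Carlo structured-coalescent simulator."""

import numpy as np
import pytest

from radintro.bsfs.data import BsfsData
from radintro.bsfs.engine import (config_probability, config_table,
                                  log_likelihood, p_ibs)
from radintro.bsfs.params import IMParams
from radintro.sim.blocks import simulate_im_block_counts, tally_counts

PARAM_SETS = [
    IMParams(1.5, 0.3, 1.2, 0.0, "none"),
    IMParams(1.5, 0.3, 1.2, 0.5, "u_to_r"),
    IMParams(1.5, 0.3, 1.2, 0.5, "r_to_u"),
    IMParams(0.4, 0.29, 2.8, 0.0, "none"),
    IMParams(0.4, 1.0, 0.5, 1.0, "u_to_r"),
]


@pytest.mark.parametrize("params", PARAM_SETS)
def test_table_is_a_distribution(params):
    """Categories (grid + absorbing tails) sum to one."""
    table = config_table(params)
    assert table.min() >= 0
    assert abs(table.sum() - 1.0) < 1e-8


def test_im_with_zero_migration_equals_div2():
    """The IM model nests strict divergence at M = 0."""
    div = config_table(IMParams(1.5, 0.3, 1.2, 0.0, "none"))
    for direction in ("u_to_r", "r_to_u"):
        im = config_table(IMParams(1.5, 0.3, 1.2, 1e-300, direction))
        np.testing.assert_allclose(im, div, rtol=1e-8, atol=1e-12)


def test_low_mutation_limit():
    """With theta -> 0 the block is monomorphic almost surely."""
    params = IMParams(1e-8, 0.3, 1.2, 0.0, "none")
    assert p_ibs(params) > 1.0 - 1e-6
    assert config_probability(params, (1, 0, 0, 0)) < 1e-6


def test_p_ibs_decreasing_in_theta():
    vals = [p_ibs(IMParams(th, 0.3, 1.2, 0.0, "none"))
            for th in (0.5, 1.0, 2.0)]
    assert vals[0] > vals[1] > vals[2]


def test_species_swap_symmetry_at_nu_one():
    """At nu = 1 relabelling the species swaps k1 and k2 and reverses the
    migration direction, leaving probabilities unchanged."""
    a = config_table(IMParams(1.0, 1.0, 0.8, 0.6, "u_to_r"))
    b = config_table(IMParams(1.0, 1.0, 0.8, 0.6, "r_to_u"))
    np.testing.assert_allclose(a, np.swapaxes(b, 0, 1), rtol=1e-8,
                               atol=1e-12)


def test_invalid_parameters_raise():
    with pytest.raises(ValueError):
        IMParams(-1.0, 0.3, 1.2, 0.0, "none")
    with pytest.raises(ValueError):
        IMParams(1.0, 0.3, 1.2, 0.5, "none")   # M > 0 without direction
    with pytest.raises(ValueError):
        IMParams(1.0, 0.3, 1.2, 0.0, "u_to_r")  # direction without M


def test_tail_lumping_matches_truncation_change():
    """Interior cells are identical across truncations; the tail cell
    equals the lumped mass of the larger grid."""
    params = IMParams(2.5, 0.5, 1.0, 0.0, "none")
    small = config_table(params, kmax=(2, 2, 2, 2))
    big = config_table(params, kmax=(4, 4, 4, 4))
    assert small[1, 0, 0, 1] == pytest.approx(big[1, 0, 0, 1], rel=1e-8)
    # tail of the small grid = sum of the big grid beyond k1 = 2
    tail = big[3:, 0, 0, 1].sum()
    assert small[3, 0, 0, 1] == pytest.approx(tail, rel=1e-6)


def test_log_likelihood_additivity_and_formula():
    params = IMParams(1.5, 0.3, 1.2, 0.0, "none")
    one = BsfsData(np.array([[1, 0, 0, 0]]))
    expected = (np.log(config_probability(params, (1, 0, 0, 0)))
                - np.log(1.0 - p_ibs(params)))
    assert log_likelihood(params, one) == pytest.approx(expected, rel=1e-10)
    two = BsfsData(np.array([[1, 0, 0, 0], [1, 0, 0, 0]]))
    assert log_likelihood(params, two) == pytest.approx(2 * expected,
                                                        rel=1e-10)


def test_log_likelihood_rejects_monomorphic_blocks():
    params = IMParams(1.5, 0.3, 1.2, 0.0, "none")
    with pytest.raises(ValueError):
        log_likelihood(params, BsfsData(np.array([[0, 0, 0, 0]])))


def test_im_likelihood_nests_div2():
    """The IM likelihood is continuous at the M -> 0 boundary (so its sup
    over M >= 0 can never fall below div2), and data generated with
    migration prefer the migration model."""
    truth = IMParams(1.0, 0.5, 1.0, 0.0, "none")
    cnt = simulate_im_block_counts(truth, 400, seed=2)
    data = BsfsData(cnt[cnt.sum(axis=1) > 0])
    base = log_likelihood(truth, data)
    at_boundary = log_likelihood(IMParams(1.0, 0.5, 1.0, 1e-6, "u_to_r"),
                                 data)
    assert at_boundary == pytest.approx(base, abs=1e-3)

    mig_truth = IMParams(1.0, 0.5, 1.0, 1.0, "u_to_r")
    cnt2 = simulate_im_block_counts(mig_truth, 600, seed=3)
    data2 = BsfsData(cnt2[cnt2.sum(axis=1) > 0])
    assert log_likelihood(mig_truth, data2) > \
        log_likelihood(truth, data2)


def test_conditional_frequency_matches_oracle():
    """P(k | variable) agrees with conditioned Monte-Carlo frequencies."""
    params = IMParams(1.5, 0.3, 1.2, 0.0, "none")
    n = 200_000
    cnt = simulate_im_block_counts(params, n, seed=99)
    var = cnt[cnt.sum(axis=1) > 0]
    freq = ((var == [1, 0, 0, 0]).all(axis=1)).mean()
    p = config_probability(params, (1, 0, 0, 0)) / (1.0 - p_ibs(params))
    se = np.sqrt(p * (1 - p) / len(var))
    assert abs(freq - p) < 4 * se


def test_monomorphic_fraction_matches_oracle():
    params = IMParams(1.5, 0.3, 1.2, 0.0, "none")
    n = 200_000
    cnt = simulate_im_block_counts(params, n, seed=7)
    frac = (cnt.sum(axis=1) == 0).mean()
    p = p_ibs(params)
    se = np.sqrt(p * (1 - p) / n)
    assert abs(frac - p) < 4 * se
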