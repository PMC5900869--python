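"""Structured-coalescent simulation of blockwise site-type counts.

Two interchangeable simulators produce per-block counts of the four
variable-site classes for one diploid individual per species:

* :func:`simulate_im_block_counts` -- a vectorised Gillespie simulation of
  the 4-lineage structured coalescent (two demes before the split, Kingman
  coalescence after), accumulating per-class branch lengths and dropping
  Poisson mutations at rate theta/2 per unit branch length.  This is the
  brute-force Monte-Carlo oracle for the analytic likelihood engine and
  runs ~10^6 blocks in seconds.
* :func:`simulate_im_blocks_msprime` -- the same contract driven by
  msprime, used to cross-check the hand-written simulator against an
  independent implementation of the structured coalescent.

Time is measured in units of 2 N_anc generations, so coalescence occurs at
rate 1 per lineage pair in the rivale deme and the ancestor, 1/nu in the
urbanum deme, and backward migration moves lineages out of the forward-time
recipient deme at rate M/2 per lineage.
"""

from __future__ import annotations

import numpy as np

from ..bsfs.data import BlockConfig
from ..bsfs.engine import TYPE_OF_COMP, DEME_R, DEME_U
from ..bsfs.params import IMParams

# genome bitmasks: bits 0,1 = the two rivale genomes; bits 2,3 = urbanum
_TYPE_OF_MASK = np.full(16, -1, dtype=np.int64)
for _m in range(1, 16):
    _a = bin(_m & 0b0011).count("1")
    _b = bin(_m >> 2).count("1")
    _t = TYPE_OF_COMP[(_a, _b)]
    _TYPE_OF_MASK[_m] = -1 if _t is None else _t

_PAIRS = [(i, j) for i in range(4) for j in range(i + 1, 4)]


def simulate_im_block_counts(params: IMParams, n_blocks: int,
                             block_length: int = 117,
                             seed=None) -> np.ndarray:
    """Simulate ``n_blocks`` independent blocks; returns (n_blocks, 4) counts."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if block_length < 1:
        raise ValueError("block_length must be >= 1")
    rng = np.random.default_rng(seed)
    n = int(n_blocks)
    theta, nu, T, M = params.theta_anc, params.nu, params.T, params.M
    if params.direction == "u_to_r":
        recipient = DEME_R
    elif params.direction == "r_to_u":
        recipient = DEME_U
    else:
        recipient = -1  # no migration

    mask = np.tile(np.array([1, 2, 4, 8], dtype=np.int64), (n, 1))
    deme = np.tile(np.array([DEME_R, DEME_R, DEME_U, DEME_U],
                            dtype=np.int64), (n, 1))
    if T == 0:
        deme[:] = DEME_R
    t_now = np.zeros(n)
    lengths = np.zeros((n, 4))  # accumulated branch length per class

    alive = np.flatnonzero((mask > 0).sum(axis=1) > 1)
    while len(alive):
        m = mask[alive]
        d = deme[alive]
        tt = t_now[alive]
        pre = tt < T

        rates = np.zeros((len(alive), 10))
        for col, (i, j) in enumerate(_PAIRS):
            ok = (m[:, i] > 0) & (m[:, j] > 0) & (d[:, i] == d[:, j])
            pair_rate = np.where(d[:, i] == DEME_U, 1.0 / nu, 1.0)
            rates[:, col] = np.where(ok, pair_rate, 0.0)
        if recipient >= 0 and M > 0:
            for i in range(4):
                ok = (m[:, i] > 0) & (d[:, i] == recipient) & pre
                rates[:, 6 + i] = np.where(ok, M / 2.0, 0.0)

        total = rates.sum(axis=1)
        # blocks with no available event before the split (e.g. lone
        # lineages in separate demes) simply wait until T
        with np.errstate(divide="ignore"):
            dt = rng.exponential(np.where(total > 0, 1.0 / np.maximum(total, 1e-300), np.inf))
        crosses = pre & (tt + dt > T)
        dt_eff = np.where(crosses, T - tt, dt)

        # accrue per-class branch length over the elapsed interval
        types = _TYPE_OF_MASK[m]
        for c in range(4):
            cnt = ((types == c) & (m > 0)).sum(axis=1)
            lengths[alive, c] += dt_eff * cnt
        t_now[alive] = tt + dt_eff

        # blocks that hit the split: merge demes, no event executed
        hit = alive[crosses]
        deme[hit] = DEME_R

        # execute the sampled event for the rest
        go = ~crosses
        if go.any():
            sub = alive[go]
            r = rates[go]
            u = rng.random(len(sub)) * total[go]
            event = (np.cumsum(r, axis=1) <= u[:, None]).sum(axis=1)
            for col, (i, j) in enumerate(_PAIRS):
                rows = sub[event == col]
                if len(rows):
                    mask[rows, i] |= mask[rows, j]
                    mask[rows, j] = 0
            for i in range(4):
                rows = sub[event == 6 + i]
                if len(rows):
                    deme[rows, i] = 1 - deme[rows, i]

        alive = alive[(mask[alive] > 0).sum(axis=1) > 1]

    return rng.poisson(theta / 2.0 * lengths)


def simulate_im_blocks(params: IMParams, n_blocks: int,
                       block_length: int = 117, seed=None):
    """Spec'd list-of-:class:`BlockConfig` wrapper around the array simulator."""
    counts = simulate_im_block_counts(params, n_blocks, block_length, seed)
    return [BlockConfig(*row) for row in counts]


def simulate_im_blocks_msprime(params: IMParams, n_blocks: int,
                               block_length: int = 117,
                               seed: int = 1) -> np.ndarray:
    """Independent msprime implementation of the same block simulator.

    Returns an (n_blocks, 4) array of per-class counts.  Population sizes
    are chosen so that one msprime time unit equals 2 N_anc generations
    (size 0.5 for the ancestor/rivale, nu/2 for urbanum).
    """
    import msprime

    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    dem = msprime.Demography()
    dem.add_population(name="riv", initial_size=0.5)
    dem.add_population(name="urb", initial_size=params.nu / 2.0)
    dem.add_population(name="anc", initial_size=0.5)
    if params.M > 0:
        # backward in time, lineages in the forward-time recipient deme
        # jump into the donor deme at rate M/2 per lineage
        recipient, donor = (("riv", "urb") if params.direction == "u_to_r"
                            else ("urb", "riv"))
        dem.set_migration_rate(source=recipient, dest=donor,
                               rate=params.M / 2.0)
    dem.add_population_split(time=max(params.T, 1e-30),
                             derived=["riv", "urb"], ancestral="anc")

    rng = np.random.default_rng(seed)
    mut_seeds = rng.integers(1, 2**31 - 1, size=n_blocks)
    reps = msprime.sim_ancestry(
        samples={"riv": 1, "urb": 1}, demography=dem, ploidy=2,
        sequence_length=block_length, discrete_genome=False,
        num_replicates=n_blocks, random_seed=int(rng.integers(1, 2**31 - 1)))
    out = np.zeros((n_blocks, 4), dtype=np.int64)
    for idx, ts in enumerate(reps):
        mts = msprime.sim_mutations(ts, rate=params.theta_anc /
                                    (2.0 * block_length),
                                    discrete_genome=False,
                                    random_seed=int(mut_seeds[idx]))
        if mts.num_sites == 0:
            continue
        G = mts.genotype_matrix()  # (sites, 4 genomes), 0 = ancestral
        derived = G > 0
        a = derived[:, :2].sum(axis=1)
        b = derived[:, 2:].sum(axis=1)
        for ai, bi in zip(a, b):
            t = TYPE_OF_COMP.get((int(ai), int(bi)))
            if t is not None:
                out[idx, t] += 1
    return out


def tally_counts(counts: np.ndarray, kmax=(4, 4, 4, 4)) -> np.ndarray:
    """Histogram simulated counts on the lumped (kmax+2)^4 category grid."""
    counts = np.asarray(counts)
    sizes = tuple(k + 2 for k in kmax)
    lumped = np.minimum(counts, np.array(kmax) + 1)
    flat = np.ravel_multi_index(tuple(lumped.T), sizes)
    return np.bincount(flat, minlength=int(np.prod(sizes))).reshape(sizes)
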