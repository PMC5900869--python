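"""Tallying blockwise site-type configurations from a genotype pair.

For one diploid individual per species, every biallelic site is classified
by the pair of genotypes: (het, hom) counts toward k1, (hom, het) toward
k2, (het, het) toward k3, opposite homozygotes toward k4, and identical
homozygotes not at all.  Sites with a missing or third-allele call in
either individual are excluded and reported.  Blocks (radtags) whose
remaining sites are all invariant between the pair are dropped — the
assembler never reports monomorphic radtags, and the model conditions the
likelihood on variable blocks accordingly — with the dropped count logged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..genotypes import GenotypeMatrix
from .data import BlockConfig, BsfsData


def assign_blocks(matrix: GenotypeMatrix, block_map: pd.DataFrame):
    """Map each site onto a block id (half-open 0-based [start, end))."""
    out = np.full(matrix.n_sites, None, dtype=object)
    by_scaf = {k: v for k, v in block_map.groupby("scaffold")}
    for j in range(matrix.n_sites):
        rows = by_scaf.get(matrix.scaffold[j])
        if rows is None:
            continue
        pos0 = matrix.position[j] - 1
        hit = rows[(rows["start"] <= pos0) & (pos0 < rows["end"])]
        if len(hit):
            out[j] = hit["block_id"].iloc[0]
    return out


def tally_blocks(matrix: GenotypeMatrix, sample_r, sample_u,
                 block_map: pd.DataFrame, block_length: int = 117):
    """Blockwise site-type tally for one diploid pair.

    Returns ``(BsfsData, report)`` where report counts excluded sites and
    dropped monomorphic blocks.
    """
    for sid in (sample_r, sample_u):
        matrix.sample_index(sid)  # raises on unknown / duplicated ids
    g_r = matrix.genotypes[matrix.sample_index(sample_r)]
    g_u = matrix.genotypes[matrix.sample_index(sample_u)]

    block_of = assign_blocks(matrix, block_map)
    configs: dict = {}
    report = {"n_sites": int(matrix.n_sites),
              "n_sites_excluded": 0,
              "n_sites_unassigned": 0,
              "n_blocks_monomorphic_dropped": 0}

    for j in range(matrix.n_sites):
        b = block_of[j]
        if b is None:
            report["n_sites_unassigned"] += 1
            continue
        configs.setdefault(b, [0, 0, 0, 0])
        gr, gu = int(g_r[j]), int(g_u[j])
        if gr < 0 or gu < 0:
            report["n_sites_excluded"] += 1
            continue
        r_het, u_het = gr == 1, gu == 1
        if r_het and u_het:
            configs[b][2] += 1
        elif r_het:
            configs[b][0] += 1
        elif u_het:
            configs[b][1] += 1
        elif gr != gu:
            configs[b][3] += 1
        # identical homozygotes contribute nothing

    rows = []
    for b, k in sorted(configs.items()):
        if sum(k) == 0:
            report["n_blocks_monomorphic_dropped"] += 1
        else:
            rows.append(k)
    if not rows:
        raise ValueError("no variable blocks to tally")
    data = BsfsData(np.array(rows), block_length)
    report["n_blocks_variable"] = data.n_blocks
    return data, report
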