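#!/usr/bin/env python
"""Between-species divergence (dxy), population structure (F_ST) and the
f3 admixture tests on the synthetic dataset.

dxy is computed per scaffold separately for allopatric and sympatric
samples (equal values argue against introgression in sympatry); f3 treats
each sympatric species sample as a potential admixture target with the
allopatric samples as sources, with 2000 scaffold bootstraps.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from radintro.genotypes import read_genotypes
from radintro.summary_stats import (allele_frequencies, dxy, f3_test, fst,
                                    paralog_filter)

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 20454


def main():
    fx = BASE / "fixture"
    m = read_genotypes(fx / "genotypes.vcf", fx / "metadata.tsv")
    allo_r = m.group_ids(species="rivale", zone="allopatric")
    allo_u = m.group_ids(species="urbanum", zone="allopatric")
    retained, _ = paralog_filter(m, allo_r, allo_u)
    mf = m.take_sites(np.isin(m.scaffold, list(retained)))

    # hybrid classes were computed in 03; exclude flagged hybrids
    hi = pd.read_csv(BASE / "hybrid_index.tsv", sep="\t")
    pure = {sp: list(hi.loc[hi["class"] == sp, "sample_id"])
            for sp in ("rivale", "urbanum")}

    bm = pd.read_csv(fx / "block_map.tsv", sep="\t")
    sites = (bm.assign(length=bm["end"] - bm["start"])
             .groupby("scaffold")["length"].sum().to_dict())
    summary = {}
    for label, (gx, gy) in {
            "allopatric": (allo_r, allo_u),
            "sympatric": (pure["rivale"], pure["urbanum"])}.items():
        r = dxy(mf, gx, gy, sites, min_called=12)
        summary[label] = {"mean": round(r.mean, 5), "se": round(r.se, 5),
                          "n_scaffolds": r.n_scaffolds}
        print(f"dxy {label}: {r.mean:.5f} +/- {r.se:.5f} "
              f"({r.n_scaffolds} scaffolds)")
    (BASE / "dxy_summary.json").write_text(json.dumps(summary, indent=2))

    groups = {}
    meta = mf.samples
    for sp in ("rivale", "urbanum"):
        sel = (meta.species == sp) & (meta.zone == "allopatric")
        for pop in sorted(set(meta.loc[sel, "population"])):
            ids = mf.group_ids(species=sp, population=pop)
            if len(ids) >= 2:
                groups[f"{sp}:{pop}"] = ids
    fst_mat = fst(mf, groups)
    fst_mat.to_csv(BASE / "fst_pairwise.tsv", sep="\t")
    for sp in ("rivale", "urbanum"):
        names = [g for g in groups if g.startswith(sp)]
        vals = [fst_mat.loc[a, b] for i, a in enumerate(names)
                for b in names[i + 1:]]
        print(f"mean pairwise F_ST among allopatric {sp} populations: "
              f"{np.nanmean(vals):.3f}")

    fa, _ = allele_frequencies(mf, allo_r, 10)
    fb, _ = allele_frequencies(mf, allo_u, 10)
    f3_out = {}
    for sp in ("rivale", "urbanum"):
        fc, _ = allele_frequencies(mf, pure[sp], 10)
        res = f3_test(fa, fb, fc, mf.scaffold, n_boot=2000, seed=SEED)
        f3_out[sp] = {"f3": round(res.f3, 5),
                      "ci": [round(res.ci_lower, 5),
                             round(res.ci_upper, 5)],
                      "n_snps": res.n_snps,
                      "significant_introgression":
                          res.significant_introgression}
        print(f"f3 target={sp}: {res.f3:.5f} "
              f"[{res.ci_lower:.5f}, {res.ci_upper:.5f}] "
              f"significant={res.significant_introgression}")
    (BASE / "f3_tests.json").write_text(json.dumps(f3_out, indent=2))


if __name__ == "__main__":
    main()
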