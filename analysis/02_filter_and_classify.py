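#!/usr/bin/env python
"""Paralog filtering and polymorphism classification.

Drops every scaffold carrying a SNP with the pooled-paralog signature
(observed heterozygosity > 0.5 or negative F_IS in either species,
computed on the allopatric samples), then classifies the surviving SNPs
into the four within/between-species polymorphism types and reports the
category mix.
"""

import json
from pathlib import Path

import numpy as np

from radintro.genotypes import read_genotypes
from radintro.summary_stats import classify_polymorphism, paralog_filter

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    fx = BASE / "fixture"
    m = read_genotypes(fx / "genotypes.vcf", fx / "metadata.tsv")
    allo_r = m.group_ids(species="rivale", zone="allopatric")
    allo_u = m.group_ids(species="urbanum", zone="allopatric")

    retained, report = paralog_filter(m, allo_r, allo_u)
    n_excl = len(set(m.scaffold)) - len(retained)
    report.to_csv(BASE / "paralog_exclusions.tsv", sep="\t", index=False)
    print(f"paralog filter: excluded {n_excl} scaffolds, "
          f"retained {len(retained)}")

    mf = m.take_sites(np.isin(m.scaffold, list(retained)))
    table = classify_polymorphism(mf, allo_r, allo_u)
    table.per_snp.to_csv(BASE / "polymorphism_classification.tsv",
                         sep="\t", index=False)
    props = {k: round(100 * v, 1) for k, v in table.proportions().items()}
    (BASE / "polymorphism_counts.json").write_text(
        json.dumps({"counts": table.counts, "percent": props}, indent=2))
    print(f"classified {table.total} SNPs: {table.counts}")
    print(f"category percentages: {props}")


if __name__ == "__main__":
    main()
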