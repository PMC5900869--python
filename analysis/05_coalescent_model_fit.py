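#!/usr/bin/env python
"""Blockwise-SFS coalescent model comparison at study scale.

Simulates 660 variable 117-bp blocks for one diploid pair under the
strict-divergence model at study-vicinity truth (N_anc = 1.3e5,
N_urb/N_anc = 0.29, split ~2.2 Myr with mu = 7e-9 and 3-year
generations), fits div2 and both isolation-with-migration directions by
maximum likelihood, compares models by delta lnL, profiles T for a 95%
support interval, and converts estimates to natural units.
"""

import json
from dataclasses import asdict
from pathlib import Path

from radintro.bsfs.data import BsfsData
from radintro.bsfs.engine import p_ibs
from radintro.bsfs.fit import compare_models, fit_model, profile_ci
from radintro.bsfs.params import IMParams
from radintro.bsfs.units import to_natural_units
from radintro.sim.blocks import simulate_im_block_counts

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 20454

MU, G, L = 7e-9, 3.0, 117
TRUTH = IMParams(4 * 1.3e5 * MU * L, 0.29, 2.2e6 / (2 * 1.3e5 * G),
                 0.0, "none")


def main():
    cnt = simulate_im_block_counts(TRUTH, 1000, seed=SEED)
    var = cnt[cnt.sum(axis=1) > 0]
    data = BsfsData(var[:660], L)
    print(f"simulated {data.n_blocks} variable blocks "
          f"({data.configs.sum()} variable sites); "
          f"p_IBS at truth = {p_ibs(TRUTH):.3f}")

    fits = [fit_model(data, mdl, seed=SEED % 2**31, n_restarts=3)
            for mdl in ("div2", "IM_u_to_r", "IM_r_to_u")]
    table = compare_models(fits)
    for row in table:
        print(f"  {row['model']:10s} delta lnL = {row['delta_lnL']:8.3f} "
              f"{'(significantly worse)' if row['significantly_worse'] else ''}")
    div2_row = next(r for r in table if r["model"] == "div2")
    if div2_row["significantly_worse"]:
        print("  note: the data were simulated WITHOUT migration; a "
              "marginal preference for an IM model (M-hat near 0) is the "
              "expected boundary likelihood-ratio chance behaviour and "
              "should not be read as evidence of gene flow")

    best = max(fits, key=lambda f: f.loglik)
    div2 = next(f for f in fits if f.model == "div2")
    ci = profile_ci(data, div2, "T", n_grid=9, seed=1)
    units = to_natural_units(div2, MU, G, L)
    print(f"div2 MLE: N_anc = {units.N_anc:.3g}, N_urb = {units.N_urb:.3g}, "
          f"t = {units.t_years:.3g} years")
    lo = to_natural_units(div2.params.with_(T=ci.lower), MU, G, L)
    hi = to_natural_units(div2.params.with_(T=ci.upper), MU, G, L)
    print(f"95% support interval for the split: "
          f"{lo.t_years:.3g} - {hi.t_years:.3g} years "
          f"(truth 2.2e6)")

    payload = {
        "truth": asdict(TRUTH),
        "comparison": table,
        "fits": [{"model": f.model, "params": asdict(f.params),
                  "loglik": f.loglik,
                  "natural_units": asdict(to_natural_units(f, MU, G, L))}
                 for f in fits],
        "T_profile_ci": {"lower": ci.lower, "upper": ci.upper,
                         "t_years": [lo.t_years, hi.t_years]},
    }
    BASE.mkdir(exist_ok=True)
    (BASE / "bsfs_model_fit.json").write_text(
        json.dumps(payload, indent=2, default=str))
    print(f"wrote {BASE / 'bsfs_model_fit.json'}")


if __name__ == "__main__":
    main()
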