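"""End-to-end orchestration: configuration, stage chaining and reports.

``run_pipeline`` chains the stages in dependency order on a VCF + sample
metadata table: paralog filtering (on the allopatric training samples),
polymorphism classification, diagnostic panel construction and validation,
per-individual hybrid indices and class calls, the introgression scans,
f3 / dxy / F_ST between the configured groups (excluding individuals
classed as hybrids, which would otherwise dominate any admixture signal),
and optionally the blockwise coalescent model fits for one diploid pair.

Every stage writes its tables under the configured output directory and
contributes counts to a run report; rerunning with the same config and
seed reproduces all outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix, read_genotypes
from . import summary_stats as ss
from . import hybrid as hy
from .bsfs.data import BsfsData
from .bsfs.tally import tally_blocks
from .bsfs.fit import fit_model, profile_ci, compare_models
from .bsfs.units import to_natural_units, DEFAULT_MU, DEFAULT_G
from .sim.genotypes import (SimSpec, simulate_genotype_dataset,
                            IntrogressionPlan)

DEFAULT_STAGES = ("paralog_filter", "classify", "panel", "hybrid_index",
                  "introgression_scan", "fst", "dxy", "f3")


@dataclass
class AnalysisConfig:
    vcf: str = ""
    metadata: str = ""
    block_map: str = ""              # BED-style TSV, optional (bsfs only)
    outdir: str = "radintro_out"
    seed: int = 0
    stages: tuple = DEFAULT_STAGES
    # stage parameters (defaults follow the study's choices)
    ho_max: float = 0.5
    fis_min: float = 0.0
    hi_threshold: float = 0.97
    n_boot: int = 2000
    min_called_f3: int = 10
    min_called_dxy: int = 12
    min_carriers: int = 3
    # bsfs options
    bsfs_pair: tuple = ()            # (rivale_sample, urbanum_sample)
    bsfs_models: tuple = ("div2", "IM_u_to_r", "IM_r_to_u")
    bsfs_kmax: tuple = (4, 4, 4, 4)
    bsfs_restarts: int = 5
    block_length: int = 117
    mu: float = DEFAULT_MU
    generation_time: float = DEFAULT_G

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("stages", "bsfs_pair", "bsfs_models", "bsfs_kmax"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("stages", "bsfs_pair", "bsfs_models", "bsfs_kmax"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str)
            .encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config_digest: str
    seed: int
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def add(self, name: str, counts: dict, outputs: list) -> None:
        if any(s["stage"] == name for s in self.stages):
            raise ValueError(f"stage {name} already recorded")
        self.stages.append({"stage": name, "counts": counts,
                            "outputs": outputs})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _json_dump(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)


def run_pipeline(config: AnalysisConfig,
                 matrix: GenotypeMatrix | None = None) -> RunReport:
    """Execute the enabled stages in dependency order; returns the report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_digest=config.digest(), seed=config.seed)
    t0 = time.time()

    if matrix is None:
        matrix = read_genotypes(config.vcf, config.metadata)
    report.add("read_genotypes",
               {"n_samples": matrix.n_samples, "n_sites": matrix.n_sites,
                "n_scaffolds": len(set(matrix.scaffold))}, [])

    allo_r = matrix.group_ids(species="rivale", zone="allopatric")
    allo_u = matrix.group_ids(species="urbanum", zone="allopatric")
    sym_ids = matrix.group_ids(zone="sympatric")

    stages = set(config.stages)
    mf = matrix
    if "paralog_filter" in stages:
        retained, rep = ss.paralog_filter(matrix, allo_r, allo_u,
                                          config.ho_max, config.fis_min)
        rep_path = out / "paralog_exclusions.tsv"
        rep.to_csv(rep_path, sep="\t", index=False)
        mf = matrix.take_sites(np.isin(matrix.scaffold, list(retained)))
        report.add("paralog_filter",
                   {"n_scaffolds_retained": len(retained),
                    "n_scaffolds_excluded":
                        len(set(matrix.scaffold)) - len(retained),
                    "n_sites_retained": mf.n_sites},
                   [str(rep_path)])

    if "classify" in stages:
        table = ss.classify_polymorphism(mf, allo_r, allo_u)
        path = out / "polymorphism_classification.tsv"
        table.per_snp.to_csv(path, sep="\t", index=False)
        report.add("classify", dict(table.counts), [str(path)])

    panel = None
    hi_table = None
    classes = {}
    if "panel" in stages:
        panel = hy.build_panel(mf, allo_r, allo_u)
        path = out / "diagnostic_panel.tsv"
        panel.primary.to_csv(path, sep="\t", index=False)
        report.add("panel", {"n_primary": panel.n_snps,
                             "n_secondary": len(panel.secondary)},
                   [str(path)])

    if "hybrid_index" in stages:
        if panel is None:
            raise RuntimeError("hybrid_index stage requires the panel stage")
        hi_table = hy.hybrid_index_table(mf, sym_ids, panel,
                                         config.hi_threshold)
        path = out / "hybrid_index.tsv"
        hi_table.to_csv(path, sep="\t", index=False)
        classes = dict(zip(hi_table["sample_id"], hi_table["class"]))
        report.add("hybrid_index",
                   {"n_scored": len(hi_table),
                    "n_hybrids":
                        int((hi_table["class"] == "hybrid").sum())},
                   [str(path)])

    if "introgression_scan" in stages:
        if not classes:
            raise RuntimeError("introgression_scan requires hybrid_index")
        cand = hy.introgression_candidates(mf, panel, classes)
        scan = hy.cosegregation_scan(cand, mf, panel, classes,
                                     config.min_carriers)
        cand.per_locus.to_csv(out / "introgression_candidate_loci.tsv",
                              sep="\t", index=False)
        _json_dump([{"loci": g.loci, "scaffolds": sorted(g.scaffolds),
                     "recipient": g.recipient, "n_carriers": g.n_carriers,
                     "carriers": g.carriers.to_dict("records"),
                     "secondary_support": g.secondary_support}
                    for g in scan], out / "cosegregation_groups.json")
        report.add("introgression_scan",
                   {"n_candidate_loci": len(cand.per_locus),
                    "n_groups": len(scan),
                    "n_partial_pairs": len(scan.partial)},
                   [str(out / "introgression_candidate_loci.tsv"),
                    str(out / "cosegregation_groups.json")])

    # pure sympatric groups (hybrids excluded where classes are known)
    def pure(species):
        ids = mf.group_ids(species=species, zone="sympatric")
        if classes:
            ids = [i for i in ids if classes.get(i) == species]
        return ids

    if "fst" in stages:
        groups = {}
        for sp in ("rivale", "urbanum"):
            for pop in sorted(set(
                    mf.samples.loc[(mf.samples.species == sp) &
                                   (mf.samples.zone == "allopatric"),
                                   "population"])):
                ids = mf.group_ids(species=sp, population=pop)
                if len(ids) >= 2:
                    groups[f"{sp}:{pop}"] = ids
        if len(groups) >= 2:
            mat = ss.fst(mf, groups)
            path = out / "fst_pairwise.tsv"
            mat.to_csv(path, sep="\t")
            within = {}
            for sp in ("rivale", "urbanum"):
                names = [g for g in groups if g.startswith(sp)]
                vals = [mat.loc[a, b] for i, a in enumerate(names)
                        for b in names[i + 1:]]
                within[sp] = float(np.nanmean(vals)) if vals else np.nan
            report.add("fst", {"n_groups": len(groups),
                               "mean_fst_rivale_pops": within["rivale"],
                               "mean_fst_urbanum_pops": within["urbanum"]},
                       [str(path)])
        else:
            report.warnings.append("fst: fewer than two populations")

    sites_per_scaffold = None
    if "dxy" in stages:
        # site universe: genotyped sites on analysed radtags per scaffold
        if config.block_map:
            bm = pd.read_csv(config.block_map, sep="\t")
            sites_per_scaffold = (bm.groupby("scaffold")
                                  .apply(lambda d: int((d["end"] -
                                                        d["start"]).sum()),
                                         include_groups=False).to_dict())
        else:
            counts = pd.Series(mf.scaffold).value_counts()
            sites_per_scaffold = {
                s: config.block_length *
                int(np.ceil(counts[s] / max(config.block_length, 1)))
                for s in counts.index}
        rows = {}
        for label, (gx, gy) in {
                "allopatric": (allo_r, allo_u),
                "sympatric": (pure("rivale"), pure("urbanum"))}.items():
            if min(len(gx), len(gy)) == 0:
                continue
            res = ss.dxy(mf, gx, gy, sites_per_scaffold,
                         config.min_called_dxy)
            res.per_scaffold.to_csv(out / f"dxy_{label}.tsv", sep="\t",
                                    index=False)
            rows[label] = {"mean": res.mean, "se": res.se,
                           "n_scaffolds": res.n_scaffolds}
        _json_dump(rows, out / "dxy_summary.json")
        report.add("dxy", {k: v["mean"] for k, v in rows.items()},
                   [str(out / "dxy_summary.json")])

    if "f3" in stages and (min(len(allo_r), len(allo_u)) <
                           config.min_called_f3):
        report.warnings.append(
            "f3: source groups smaller than min_called_f3; stage skipped")
    elif "f3" in stages:
        fa, _ = ss.allele_frequencies(mf, allo_r, config.min_called_f3)
        fb, _ = ss.allele_frequencies(mf, allo_u, config.min_called_f3)
        f3_out = {}
        for target_sp in ("rivale", "urbanum"):
            ids = pure(target_sp)
            if len(ids) < config.min_called_f3:
                report.warnings.append(
                    f"f3: target {target_sp} has too few individuals")
                continue
            fc, _ = ss.allele_frequencies(mf, ids, config.min_called_f3)
            res = ss.f3_test(fa, fb, fc, mf.scaffold,
                             n_boot=config.n_boot, seed=config.seed)
            f3_out[target_sp] = {
                "f3": res.f3, "ci": [res.ci_lower, res.ci_upper],
                "n_snps": res.n_snps, "n_scaffolds": res.n_scaffolds,
                "significant_introgression": res.significant_introgression}
        _json_dump(f3_out, out / "f3_tests.json")
        report.add("f3", {k: v["f3"] for k, v in f3_out.items()},
                   [str(out / "f3_tests.json")])

    if "bsfs" in stages:
        if len(config.bsfs_pair) != 2:
            raise ValueError("bsfs stage requires bsfs_pair = "
                             "(rivale_sample, urbanum_sample)")
        if not config.block_map:
            raise ValueError("bsfs stage requires a block map")
        bm = pd.read_csv(config.block_map, sep="\t")
        data, tly = tally_blocks(mf, *config.bsfs_pair, bm,
                                 config.block_length)
        fits = []
        for model in config.bsfs_models:
            fits.append(fit_model(data, model, kmax=config.bsfs_kmax,
                                  n_restarts=config.bsfs_restarts,
                                  seed=config.seed))
        table = compare_models(fits) if len(fits) > 1 else []
        result = {
            "tally": tly,
            "fits": [{
                "model": f.model,
                "params": asdict(f.params),
                "loglik": f.loglik,
                "natural_units": asdict(to_natural_units(
                    f, config.mu, config.generation_time,
                    config.block_length)),
            } for f in fits],
            "comparison": table,
        }
        _json_dump(result, out / "bsfs_fits.json")
        report.add("bsfs", {"n_blocks": data.n_blocks,
                            "best_model": max(
                                fits, key=lambda f: f.loglik).model},
                   [str(out / "bsfs_fits.json")])

    report.add("finish", {"elapsed_s": round(time.time() - t0, 2)}, [])
    report.to_json(out / "run_report.json")
    return report


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

FIXTURE_PROFILES = ("tiny", "paper_scale")


def fixture_spec(profile: str) -> SimSpec:
    if profile == "tiny":
        return SimSpec(n_scaffolds=20, radtags_per_scaffold=1.0,
                       mean_snps_per_radtag=3.0,
                       n_allopatric_r=6, n_allopatric_u=6,
                       n_sympatric_r=13, n_sympatric_u=13,
                       n_populations_r=2, n_populations_u=2,
                       paralog_scaffold_frac=0.1, missing_rate=0.02,
                       hybrid_pedigrees=(("F1", 1), ("BC1_r", 1)))
    if profile == "paper_scale":
        return SimSpec(hybrid_pedigrees=(("F1_selfed", 2), ("BC1_r", 1),
                                         ("BC1_r_selfed", 1)),
                       introgressed_block=IntrogressionPlan())
    raise ValueError(
        f"unknown profile {profile!r}; choose from {FIXTURE_PROFILES}")


def make_fixture(profile: str, seed: int, outdir) -> dict:
    """Write a synthetic dataset (VCF, metadata, block map, truth) to disk."""
    spec = fixture_spec(profile)
    matrix, truth = simulate_genotype_dataset(spec, seed=seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "metadata": out / "metadata.tsv",
        "block_map": out / "block_map.tsv",
        "truth_samples": out / "truth_samples.tsv",
        "truth_scaffolds": out / "truth_scaffolds.tsv",
        "truth_snps": out / "truth_snps.tsv",
    }
    matrix.to_vcf(paths["vcf"])
    matrix.write_metadata(paths["metadata"])
    truth.block_map.to_csv(paths["block_map"], sep="\t", index=False)
    truth.samples.to_csv(paths["truth_samples"], sep="\t", index=False)
    truth.scaffolds.to_csv(paths["truth_scaffolds"], sep="\t", index=False)
    truth.snps.to_csv(paths["truth_snps"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
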