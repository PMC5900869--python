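"""Synthetic scaffold-structured genotype datasets with known ground truth.

The generator emulates the statistical structure of stacks-genotyped ddRAD
data for a pair of hybridizing sister taxa: 117-bp radtags arranged on
scaffolds; SNPs drawn from four true categories (alternately fixed,
polymorphic in one species only, shared); contrasting inbreeding in the
two species (genotype frequencies p^2 + Fpq, 2pq(1-F), q^2 + Fpq);
among-population structure in the allopatric samples (Balding-Nichols);
paralog-contaminated scaffolds whose pooled-read artefact shows up as
excess heterozygosity; early-generation hybrids built by Mendelian gamete
sampling; and missing genotypes dropped uniformly at random.

Every latent label (per-SNP true category, per-scaffold paralog flag,
per-individual pedigree, planted introgressed haplotype carriers) is
returned in a :class:`SimTruth` for use as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ..genotypes import GenotypeMatrix, MISSING

HYBRID_CLASSES = ("F1", "F1_selfed", "BC1_r", "BC1_r_selfed")

CATEGORIES = ("alternately_fixed", "poly_r_only", "poly_u_only",
              "shared_poly")


@dataclass
class IntrogressionPlan:
    """A co-segregating donor haplotype planted in pure recipients."""
    n_scaffolds: int = 2
    n_hom_carriers: int = 6
    n_het_carriers: int = 1
    recipient: str = "urbanum"


@dataclass
class SimSpec:
    n_scaffolds: int = 500
    radtags_per_scaffold: float = 1.32
    block_length: int = 117
    mean_snps_per_radtag: float = 2.1
    n_allopatric_r: int = 14
    n_allopatric_u: int = 22
    n_sympatric_r: int = 46
    n_sympatric_u: int = 46
    # true SNP category mix (remainder of the unit interval = monomorphic,
    # i.e. no SNP emitted); defaults follow the observed 488:1334:338:34 mix
    frac_alt_fixed: float = 488 / 2194
    frac_poly_r: float = 1334 / 2194
    frac_poly_u: float = 338 / 2194
    frac_shared: float = 34 / 2194
    # within-species allele-frequency law (U-shaped by default)
    beta_a: float = 0.5
    beta_b: float = 0.5
    selfing_F_r: float = 0.25
    selfing_F_u: float = 0.95
    n_populations_r: int = 3
    n_populations_u: int = 10
    fst_pops_r: float = 0.13
    fst_pops_u: float = 0.38
    paralog_scaffold_frac: float = 0.04
    artefact_het_prob: float = 0.9
    missing_rate: float = 0.05
    hybrid_pedigrees: tuple = ()
    introgressed_block: IntrogressionPlan | None = None
    seed: int | None = None

    def validate(self) -> None:
        props = dict(frac_alt_fixed=self.frac_alt_fixed,
                     frac_poly_r=self.frac_poly_r,
                     frac_poly_u=self.frac_poly_u,
                     frac_shared=self.frac_shared,
                     paralog_scaffold_frac=self.paralog_scaffold_frac,
                     artefact_het_prob=self.artefact_het_prob,
                     missing_rate=self.missing_rate,
                     selfing_F_r=self.selfing_F_r,
                     selfing_F_u=self.selfing_F_u,
                     fst_pops_r=self.fst_pops_r,
                     fst_pops_u=self.fst_pops_u)
        for name, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = (self.frac_alt_fixed + self.frac_poly_r +
                 self.frac_poly_u + self.frac_shared)
        if total > 1.0 + 1e-12:
            raise ValueError("SNP category fractions exceed 1")
        counts = dict(n_scaffolds=self.n_scaffolds,
                      n_allopatric_r=self.n_allopatric_r,
                      n_allopatric_u=self.n_allopatric_u,
                      n_sympatric_r=self.n_sympatric_r,
                      n_sympatric_u=self.n_sympatric_u,
                      block_length=self.block_length)
        for name, v in counts.items():
            if v < 0 or (name in ("n_scaffolds", "block_length") and v < 1):
                raise ValueError(f"{name} must be non-negative, got {v}")
        for cls, cnt in self.hybrid_pedigrees:
            if cls not in HYBRID_CLASSES:
                raise ValueError(f"unknown hybrid class {cls!r}")
            if cnt < 0:
                raise ValueError("hybrid counts must be >= 0")
        n_hyb = sum(c for _, c in self.hybrid_pedigrees)
        if n_hyb and self.frac_alt_fixed == 0:
            raise ValueError(
                "hybrids requested but no alternately fixed "
                "(species-diagnostic) sites are being generated")


@dataclass
class SimTruth:
    spec: SimSpec
    samples: pd.DataFrame        # sample_id, pedigree_class
    scaffolds: pd.DataFrame      # scaffold, paralog, introgressed
    snps: pd.DataFrame           # scaffold, position, category, q_r, q_u
    block_map: pd.DataFrame      # scaffold, start (0-based), end, block_id
    introgression_carriers: pd.DataFrame  # sample_id, state

    @property
    def paralog_scaffolds(self) -> set:
        return set(self.scaffolds.loc[self.scaffolds["paralog"], "scaffold"])

    @property
    def introgressed_scaffolds(self) -> set:
        return set(
            self.scaffolds.loc[self.scaffolds["introgressed"], "scaffold"])

    def hybrids(self) -> list:
        sel = self.samples["pedigree_class"].isin(HYBRID_CLASSES)
        return list(self.samples.loc[sel, "sample_id"])


def _gamete(genotypes: np.ndarray, rng) -> np.ndarray:
    """One haploid gamete per site from unphased diploid codes."""
    g = np.asarray(genotypes)
    allele = (g == 2).astype(np.int8)
    het = g == 1
    allele[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return allele


def cross(parent_a: np.ndarray, parent_b: np.ndarray,
          selfing_generations: int = 0, seed=None, rng=None) -> np.ndarray:
    """Mendelian cross of two genotype rows, then optional selfing rounds.

    Each site segregates independently; a site missing in either parent is
    missing in the offspring.
    """
    parent_a = np.asarray(parent_a)
    parent_b = np.asarray(parent_b)
    if parent_a.shape != parent_b.shape:
        raise ValueError("parents must share the same site set")
    if selfing_generations < 0:
        raise ValueError("selfing_generations must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    bad = (parent_a < 0) | (parent_b < 0)
    child = _gamete(parent_a, rng) + _gamete(parent_b, rng)
    for _ in range(int(selfing_generations)):
        child = _gamete(child, rng) + _gamete(child, rng)
    child = child.astype(np.int8)
    child[bad] = MISSING
    return child


def _genotype_draw(p, F, n_ind, rng) -> np.ndarray:
    """Genotypes under inbreeding: P(het) = 2pq(1-F), homs get +Fpq each."""
    p = np.asarray(p)
    q = 1.0 - p
    fpq = F * p * q
    p_hom_alt = p * p + fpq
    p_het = 2.0 * p * q * (1.0 - F)
    u = rng.random((n_ind, len(p)))
    g = np.zeros((n_ind, len(p)), dtype=np.int8)
    g[u < p_hom_alt] = 2
    g[(u >= p_hom_alt) & (u < p_hom_alt + p_het)] = 1
    return g


def _balding_nichols(q, fst, rng):
    """Population-specific frequency around the species frequency q."""
    if fst <= 0:
        return np.asarray(q, dtype=float)
    q = np.asarray(q, dtype=float)
    out = q.copy()
    seg = (q > 0) & (q < 1)
    c = (1.0 - fst) / fst
    out[seg] = rng.beta(q[seg] * c, (1.0 - q[seg]) * c)
    return out


def simulate_genotype_dataset(spec: SimSpec, seed=None):
    """Draw a full synthetic dataset; returns (GenotypeMatrix, SimTruth)."""
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)

    # --- radtag / SNP scaffolding ---------------------------------------
    scaffold_names = np.array(
        [f"scaffold_{i:05d}" for i in range(spec.n_scaffolds)])
    extra = max(spec.radtags_per_scaffold - 1.0, 0.0)
    tags_per_scaf = 1 + rng.poisson(extra, size=spec.n_scaffolds)

    blocks = []
    snp_scaf, snp_pos, snp_block = [], [], []
    block_id = 0
    for si, name in enumerate(scaffold_names):
        for t in range(tags_per_scaf[si]):
            start0 = t * 10_000
            blocks.append((name, start0, start0 + spec.block_length,
                           f"block_{block_id:06d}"))
            n_snps = rng.poisson(spec.mean_snps_per_radtag)
            if n_snps > 0:
                offs = np.sort(rng.choice(spec.block_length,
                                          size=min(n_snps, spec.block_length),
                                          replace=False))
                for o in offs:
                    snp_scaf.append(name)
                    snp_pos.append(start0 + int(o) + 1)  # 1-based
                    snp_block.append(f"block_{block_id:06d}")
            block_id += 1
    block_map = pd.DataFrame(blocks,
                             columns=["scaffold", "start", "end", "block_id"])
    n_snp_raw = len(snp_pos)
    if n_snp_raw == 0:
        raise ValueError("spec produced no SNPs; increase density")

    # --- true categories and species frequencies ------------------------
    probs = np.array([spec.frac_alt_fixed, spec.frac_poly_r,
                      spec.frac_poly_u, spec.frac_shared])
    rest = max(0.0, 1.0 - probs.sum())
    cat_idx = rng.choice(5, size=n_snp_raw, p=np.append(probs, rest))
    keep = cat_idx < 4  # drop monomorphic draws: they never appear as SNPs
    cat_idx = cat_idx[keep]
    snp_scaf = np.array(snp_scaf)[keep]
    snp_pos = np.array(snp_pos)[keep]
    snp_block = np.array(snp_block)[keep]
    n_snp = len(cat_idx)

    q_r = np.zeros(n_snp)
    q_u = np.zeros(n_snp)
    beta = lambda n: rng.beta(spec.beta_a, spec.beta_b, size=n)
    coin = lambda n: rng.integers(0, 2, size=n).astype(float)
    af = cat_idx == 0
    q_r[af] = coin(af.sum())
    q_u[af] = 1.0 - q_r[af]
    pr = cat_idx == 1
    q_r[pr] = beta(pr.sum())
    q_u[pr] = coin(pr.sum())
    pu = cat_idx == 2
    q_u[pu] = beta(pu.sum())
    q_r[pu] = coin(pu.sum())
    sh = cat_idx == 3
    q_r[sh] = beta(sh.sum())
    q_u[sh] = beta(sh.sum())

    # --- individuals -----------------------------------------------------
    rows, ids, species, pops, zones, pedigree = [], [], [], [], [], []

    def add(row, sid, sp, pop, zone, ped):
        rows.append(row)
        ids.append(sid)
        species.append(sp)
        pops.append(pop)
        zones.append(zone)
        pedigree.append(ped)

    # allopatric samples with among-population structure
    for sp, n_ind, n_pops, fst, F, q in (
            ("rivale", spec.n_allopatric_r, spec.n_populations_r,
             spec.fst_pops_r, spec.selfing_F_r, q_r),
            ("urbanum", spec.n_allopatric_u, spec.n_populations_u,
             spec.fst_pops_u, spec.selfing_F_u, q_u)):
        tag = sp[0]
        if n_ind == 0:
            continue
        n_pops = max(1, min(n_pops, n_ind))
        sizes = np.full(n_pops, n_ind // n_pops)
        sizes[: n_ind % n_pops] += 1
        k = 0
        for pi, sz in enumerate(sizes):
            p_pop = _balding_nichols(q, fst, rng)
            g = _genotype_draw(p_pop, F, sz, rng)
            for i in range(sz):
                add(g[i], f"{tag}_allo_{k:02d}", sp,
                    f"{tag}_pop_{pi + 1}", "allopatric", f"parental_{tag}")
                k += 1

    # sympatric samples (single deme per species)
    for sp, n_ind, F, q in (("rivale", spec.n_sympatric_r,
                             spec.selfing_F_r, q_r),
                            ("urbanum", spec.n_sympatric_u,
                             spec.selfing_F_u, q_u)):
        tag = sp[0]
        if n_ind == 0:
            continue
        g = _genotype_draw(q, F, n_ind, rng)
        for i in range(n_ind):
            add(g[i], f"{tag}_sym_{i:02d}", sp,
                f"sym_{tag}", "sympatric", f"parental_{tag}")

    # hybrids by Mendelian gamete sampling
    hyb_count = 0
    for cls, cnt in spec.hybrid_pedigrees:
        for _ in range(cnt):
            pa = _genotype_draw(q_r, spec.selfing_F_r, 1, rng)[0]
            pb = _genotype_draw(q_u, spec.selfing_F_u, 1, rng)[0]
            if cls == "F1":
                g = cross(pa, pb, 0, rng=rng)
            elif cls == "F1_selfed":
                g = cross(pa, pb, 1, rng=rng)
            else:
                f1 = cross(pa, pb, 0, rng=rng)
                pr2 = _genotype_draw(q_r, spec.selfing_F_r, 1, rng)[0]
                gens = 1 if cls == "BC1_r_selfed" else 0
                g = cross(f1, pr2, gens, rng=rng)
            # morphology-style field label: majority ancestry
            sp = "rivale" if cls.startswith("BC1") else (
                "rivale" if hyb_count % 2 == 0 else "urbanum")
            add(g, f"hyb_{cls}_{hyb_count:02d}", sp, "sym_mixed",
                "sympatric", cls)
            hyb_count += 1

    G = np.array(rows, dtype=np.int8)
    n_ind_total = len(ids)

    # --- paralog artefact scaffolds --------------------------------------
    n_paralog = int(round(spec.paralog_scaffold_frac * spec.n_scaffolds))
    paralog_set = set(rng.choice(spec.n_scaffolds, size=n_paralog,
                                 replace=False)) if n_paralog else set()
    paralog_names = {scaffold_names[i] for i in paralog_set}
    if paralog_names:
        cols = np.flatnonzero(np.isin(snp_scaf, list(paralog_names)))
        for c in cols:
            het = rng.random(n_ind_total) < spec.artefact_het_prob
            hom = rng.integers(0, 2, size=n_ind_total).astype(np.int8) * 2
            G[:, c] = np.where(het, 1, hom)

    # --- planted introgressed haplotype ----------------------------------
    carriers = pd.DataFrame(columns=["sample_id", "state"])
    intro_names: set = set()
    plan = spec.introgressed_block
    if plan is not None:
        rec_sp = plan.recipient
        rec_tag = rec_sp[0]
        rec_ids = [i for i, (sp, z, ped) in
                   enumerate(zip(species, zones, pedigree))
                   if sp == rec_sp and z == "sympatric"
                   and ped == f"parental_{rec_tag}"]
        n_carriers = plan.n_hom_carriers + plan.n_het_carriers
        if len(rec_ids) < n_carriers:
            raise ValueError("not enough sympatric recipients to plant the "
                             "introgressed block")
        # a planted block is only taggable by the one-SNP-per-scaffold
        # panel if the scaffold's first SNP is truly alternately fixed
        # (a true fixed difference is always observed as one), so choose
        # scaffolds whose lowest-position SNP is diagnostic
        first_idx = (pd.DataFrame({"scaffold": snp_scaf,
                                   "position": snp_pos,
                                   "idx": np.arange(n_snp)})
                     .sort_values(["scaffold", "position"])
                     .groupby("scaffold", sort=False).head(1))
        candidates = [s for s, i in zip(first_idx["scaffold"],
                                        first_idx["idx"])
                      if af[i] and s not in paralog_names]
        if len(candidates) < plan.n_scaffolds:
            raise ValueError("not enough scaffolds whose first SNP is "
                             "alternately fixed to plant the "
                             "introgressed block")
        chosen = list(rng.choice(candidates, size=plan.n_scaffolds,
                                 replace=False))
        intro_names = set(chosen)
        picked = rng.choice(rec_ids, size=n_carriers, replace=False)
        hom_ids, het_ids = picked[:plan.n_hom_carriers], \
            picked[plan.n_hom_carriers:]
        cols = np.flatnonzero(np.isin(snp_scaf, chosen) & af)
        donor_is_r = rec_sp == "urbanum"
        for c in cols:
            donor_code = (2 if (q_r[c] if donor_is_r else q_u[c]) == 1.0
                          else 0)
            G[hom_ids, c] = donor_code
            G[het_ids, c] = 1
        carriers = pd.DataFrame(
            {"sample_id": [ids[i] for i in picked],
             "state": ["hom"] * len(hom_ids) + ["het"] * len(het_ids)})

    # --- missing data, uniformly at random -------------------------------
    if spec.missing_rate > 0:
        drop = rng.random(G.shape) < spec.missing_rate
        G[drop] = MISSING

    # --- assemble ---------------------------------------------------------
    ref = np.array(["A"] * n_snp)
    alt = np.array(["T"] * n_snp)
    meta = pd.DataFrame({"sample_id": ids, "species": species,
                         "population": pops, "zone": zones})
    matrix = GenotypeMatrix(G, snp_scaf, snp_pos, ref, alt, meta)

    cat_names = np.array(CATEGORIES)[cat_idx].astype(object)
    cat_names[np.isin(snp_scaf, list(paralog_names))] = "paralog_artefact"
    truth = SimTruth(
        spec=spec,
        samples=pd.DataFrame({"sample_id": ids,
                              "pedigree_class": pedigree}),
        scaffolds=pd.DataFrame({
            "scaffold": scaffold_names,
            "paralog": [s in paralog_names for s in scaffold_names],
            "introgressed": [s in intro_names for s in scaffold_names]}),
        snps=pd.DataFrame({"scaffold": snp_scaf, "position": snp_pos,
                           "block_id": snp_block, "category": cat_names,
                           "q_r": q_r, "q_u": q_u}),
        block_map=block_map,
        introgression_carriers=carriers)
    return matrix, truth
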