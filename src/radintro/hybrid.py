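"""Species-diagnostic SNP panels, hybrid indices and introgression scans.

A diagnostic panel is built from alternately fixed SNPs in allopatric
training samples (one "primary" SNP per scaffold — the first by position —
to minimise linkage; all alternately fixed SNPs are kept as a secondary
panel for confirming candidate blocks).  The panel is validated on holdout
individuals: any SNP at which a holdout is homozygous for the allele of the
*other* species is evidently not fixed between species and is removed.

The hybrid index of an individual is the fraction of its alleles at panel
SNPs that derive from the outcrossing species:

    HI = (2 * hom_r + het) / (2 * n)

Individuals with HI > 0.97 are classed as rivale, HI < 0.03 as urbanum,
anything else as a hybrid.  Pure-classed individuals carrying alleles
diagnostic for the other species are candidate targets of introgression;
candidate loci whose genotype-state vectors are identical across all
recipients, and which span at least two scaffolds, form co-segregation
groups — the signature of an un-recombined introgressed chunk of genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .summary_stats import classify_polymorphism

HI_THRESHOLD = 0.97


@dataclass
class DiagnosticPanel:
    primary: pd.DataFrame    # scaffold, position, rivale_allele, urbanum_allele
    secondary: pd.DataFrame  # all alternately fixed SNPs, same columns
    provenance: dict = field(default_factory=dict)
    validation_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["scaffold", "position", "reason"]))

    @property
    def n_snps(self) -> int:
        return len(self.primary)

    def site_mask(self, matrix: GenotypeMatrix,
                  secondary: bool = False) -> np.ndarray:
        table = self.secondary if secondary else self.primary
        keys = set(zip(table["scaffold"], table["position"]))
        return np.array([(s, p) in keys for s, p in
                         zip(matrix.scaffold, matrix.position)])


@dataclass
class HybridIndexResult:
    sample_id: str
    hom_r: int
    het: int
    hom_u: int
    n_excluded: int = 0

    @property
    def n_loci(self) -> int:
        return self.hom_r + self.het + self.hom_u

    @property
    def hybrid_index(self) -> float:
        n = self.n_loci
        if n == 0:
            return np.nan
        return (2 * self.hom_r + self.het) / (2.0 * n)

    @property
    def percent_rivale(self) -> float:
        return round(100.0 * self.hybrid_index, 1)


def build_panel(matrix: GenotypeMatrix, group_r, group_u) -> DiagnosticPanel:
    """Alternately fixed SNPs between the two training groups.

    The primary panel keeps one SNP per scaffold: the first by ascending
    1-based position (ties broken by allele lexicographic order, though
    positions are unique in practice).  Note this choice biases against
    larger, better-assembled scaffolds contributing more markers.
    """
    table = classify_polymorphism(matrix, group_r, group_u)
    fixed = table.per_snp["category"].to_numpy() == "alternately_fixed"
    if not fixed.any():
        import warnings
        warnings.warn("no alternately fixed SNPs between training groups; "
                      "panel is empty")
    idx = np.flatnonzero(fixed)
    # rivale allele = the allele fixed in the rivale training samples
    g_r = matrix.rows(group_r)[:, idx]
    riv_alt = np.where(g_r >= 0, g_r, 0).sum(axis=0) > 0
    rows = pd.DataFrame({
        "scaffold": matrix.scaffold[idx],
        "position": matrix.position[idx],
        "rivale_allele": np.where(riv_alt, matrix.alt[idx], matrix.ref[idx]),
        "urbanum_allele": np.where(riv_alt, matrix.ref[idx], matrix.alt[idx]),
        "rivale_is_alt": riv_alt,
    }).sort_values(["scaffold", "position", "rivale_allele"],
                   kind="stable").reset_index(drop=True)
    primary = rows.groupby("scaffold", sort=True).head(1).reset_index(
        drop=True)
    return DiagnosticPanel(
        primary=primary, secondary=rows,
        provenance={"training_r": list(group_r), "training_u": list(group_u)})


def _panel_columns(matrix: GenotypeMatrix, table: pd.DataFrame):
    key = {(s, p): j for j, (s, p) in
           enumerate(zip(matrix.scaffold, matrix.position))}
    cols = []
    for s, p in zip(table["scaffold"], table["position"]):
        if (s, p) not in key:
            raise KeyError(f"panel SNP {s}:{p} absent from matrix")
        cols.append(key[(s, p)])
    return np.array(cols, dtype=int)


def _opposite_hom_code(table: pd.DataFrame, holdout_species: str):
    """Genotype code meaning 'homozygous for the other species' allele'."""
    riv_alt = table["rivale_is_alt"].to_numpy()
    if holdout_species == "urbanum":
        return np.where(riv_alt, 2, 0)   # hom for the rivale allele
    if holdout_species == "rivale":
        return np.where(riv_alt, 0, 2)   # hom for the urbanum allele
    raise ValueError("holdout_species must be 'rivale' or 'urbanum'")


def validate_panel(panel: DiagnosticPanel, matrix: GenotypeMatrix,
                   holdout_ids, holdout_species: str) -> DiagnosticPanel:
    """Remove panel SNPs contradicted by holdout individuals.

    A SNP is removed when any holdout individual (of known species, not
    used for training) is homozygous for the putative allele of the other
    species; heterozygous holdouts do not trigger removal (they could be
    genuine hybridity rather than a mis-ascertained SNP).
    """
    if len(holdout_ids) == 0:
        import warnings
        warnings.warn("empty holdout set; panel returned unvalidated")
        return panel
    trained = set(panel.provenance.get("training_r", [])) | \
        set(panel.provenance.get("training_u", []))
    overlap = trained & set(holdout_ids)
    if overlap:
        raise ValueError(f"holdout overlaps training samples: {overlap}")

    logs = []
    out = {}
    for name in ("primary", "secondary"):
        table = getattr(panel, name)
        if len(table) == 0:
            out[name] = table
            continue
        cols = _panel_columns(matrix, table)
        g = matrix.rows(holdout_ids)[:, cols]
        bad_code = _opposite_hom_code(table, holdout_species)
        bad = (g == bad_code[None, :]).any(axis=0)
        out[name] = table.loc[~bad].reset_index(drop=True)
        if name == "primary":
            removed = table.loc[bad]
            for _, r in removed.iterrows():
                logs.append((r["scaffold"], r["position"],
                             f"holdout {holdout_species} homozygous for "
                             "opposite-species allele"))
    log = pd.DataFrame(logs, columns=["scaffold", "position", "reason"])
    return DiagnosticPanel(primary=out["primary"], secondary=out["secondary"],
                           provenance={**panel.provenance,
                                       "holdout": list(holdout_ids)},
                           validation_log=pd.concat(
                               [panel.validation_log, log],
                               ignore_index=True))


def hybrid_index(matrix: GenotypeMatrix, sample_id,
                 panel: DiagnosticPanel) -> HybridIndexResult:
    """Genotype-class tabulation and hybrid index for one individual.

    Loci with missing or third-allele genotypes are excluded and the index
    renormalised over the remaining loci.
    """
    cols = _panel_columns(matrix, panel.primary)
    if len(cols) == 0:
        raise ValueError("panel is empty")
    g = matrix.genotypes[matrix.sample_index(sample_id), cols]
    callable_ = g >= 0
    riv_alt = panel.primary["rivale_is_alt"].to_numpy()
    hom_r_code = np.where(riv_alt, 2, 0)
    gg = g[callable_]
    hr = int((gg == hom_r_code[callable_]).sum())
    het = int((gg == 1).sum())
    hu = int(len(gg) - hr - het)
    return HybridIndexResult(sample_id=sample_id, hom_r=hr, het=het,
                             hom_u=hu, n_excluded=int((~callable_).sum()))


def classify_individual(result: HybridIndexResult,
                        threshold: float = HI_THRESHOLD) -> str:
    """rivale if HI > threshold, urbanum if HI < 1 - threshold, else hybrid."""
    hi = result.hybrid_index
    if np.isnan(hi):
        raise ValueError(f"{result.sample_id}: no scorable panel loci")
    if hi > threshold:
        return "rivale"
    if hi < 1.0 - threshold:
        return "urbanum"
    return "hybrid"


def hybrid_index_table(matrix: GenotypeMatrix, sample_ids,
                       panel: DiagnosticPanel,
                       threshold: float = HI_THRESHOLD) -> pd.DataFrame:
    rows = []
    for sid in sample_ids:
        r = hybrid_index(matrix, sid, panel)
        rows.append({"sample_id": sid, "percent_rivale": r.percent_rivale,
                     "hom_r": r.hom_r, "het": r.het, "hom_u": r.hom_u,
                     "n_loci": r.n_loci, "n_excluded": r.n_excluded,
                     "class": classify_individual(r, threshold)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# introgression candidates and co-segregation
# ---------------------------------------------------------------------------

@dataclass
class IntrogressionCandidates:
    per_individual: pd.DataFrame  # sample_id, class, scaffold, position, n_opposite_alleles
    per_locus: pd.DataFrame       # scaffold, position, recipient, carrier_freq, n_carriers

    def alleles_carried(self, sample_id) -> int:
        sel = self.per_individual["sample_id"] == sample_id
        return int(self.per_individual.loc[sel, "n_opposite_alleles"].sum())


def introgression_candidates(matrix: GenotypeMatrix, panel: DiagnosticPanel,
                             classes: dict) -> IntrogressionCandidates:
    """Opposite-species alleles carried by pure-classed individuals.

    ``classes`` maps sample_id -> class call from :func:`classify_individual`.
    For each pure individual, every panel locus where it carries one (het)
    or two (hom) alleles diagnostic for the other species is listed; the
    per-locus carrier frequency is the opposite-allele frequency among
    called pure individuals of that recipient species.
    """
    cols = _panel_columns(matrix, panel.primary)
    riv_alt = panel.primary["rivale_is_alt"].to_numpy()
    rows = []
    locus_counts = {}
    for species in ("rivale", "urbanum"):
        ids = [s for s, c in classes.items() if c == species]
        if not ids:
            continue
        g = matrix.rows(ids)[:, cols]
        opp_hom = _opposite_hom_code(panel.primary, species)
        n_opp = np.zeros_like(g)
        n_opp[g == 1] = 1
        n_opp[g == opp_hom[None, :]] = 2
        n_opp[g < 0] = 0
        called = (g >= 0).sum(axis=0)
        tot_opp = n_opp.sum(axis=0)
        for j in np.flatnonzero(tot_opp > 0):
            locus_counts[(panel.primary["scaffold"].iloc[j],
                          int(panel.primary["position"].iloc[j]),
                          species)] = (
                int(tot_opp[j]), int(called[j]),
                int((n_opp[:, j] > 0).sum()))
        for i, sid in enumerate(ids):
            for j in np.flatnonzero(n_opp[i] > 0):
                rows.append({"sample_id": sid, "class": species,
                             "scaffold": panel.primary["scaffold"].iloc[j],
                             "position": int(
                                 panel.primary["position"].iloc[j]),
                             "state": "het" if g[i, j] == 1 else "hom",
                             "n_opposite_alleles": int(n_opp[i, j])})
    per_ind = pd.DataFrame(rows, columns=["sample_id", "class", "scaffold",
                                          "position", "state",
                                          "n_opposite_alleles"])
    per_locus = pd.DataFrame(
        [{"scaffold": s, "position": p, "recipient": sp,
          "carrier_freq": cnt / (2.0 * n) if n else np.nan,
          "n_carriers": n_car}
         for (s, p, sp), (cnt, n, n_car) in locus_counts.items()],
        columns=["scaffold", "position", "recipient", "carrier_freq",
                 "n_carriers"])
    return IntrogressionCandidates(per_ind, per_locus)


@dataclass
class CosegregationGroup:
    loci: list                   # (scaffold, position) pairs
    scaffolds: set
    carriers: pd.DataFrame       # sample_id, state vector summary
    recipient: str
    association: str             # "complete" (identical genotype vectors)
    n_carriers: int
    secondary_support: list = field(default_factory=list)


@dataclass
class CosegregationScan:
    groups: list                 # complete CosegregationGroup entries
    partial: list                # dicts with locus pair + mismatch count

    def __iter__(self):
        return iter(self.groups)

    def __len__(self):
        return len(self.groups)

    def __getitem__(self, i):
        return self.groups[i]


def cosegregation_scan(candidates: IntrogressionCandidates,
                       matrix: GenotypeMatrix, panel: DiagnosticPanel,
                       classes: dict,
                       min_carriers: int = 3) -> CosegregationScan:
    """Group candidate loci with identical genotype-state vectors.

    Loci qualify when their opposite-allele genotype-state vector across
    all pure recipients of one species is identical (complete association)
    and the group spans at least two scaffolds with at least
    ``min_carriers`` carrier individuals.  Each group is augmented with
    secondary-panel SNPs on member scaffolds that show the same complete
    association; pairs of candidate loci that share carriers but mismatch
    are reported via the ``partial`` attribute on the returned list.
    """
    groups = []
    partial = []
    for species in ("rivale", "urbanum"):
        ids = [s for s, c in classes.items() if c == species]
        if not ids:
            continue
        sub = candidates.per_locus[
            candidates.per_locus["recipient"] == species]
        loci = [(s, p) for s, p in zip(sub["scaffold"], sub["position"])]
        if not loci:
            continue
        g = matrix.rows(ids)
        opp_state = {}
        for (s, p) in loci:
            j = int(np.flatnonzero((matrix.scaffold == s) &
                                   (matrix.position == p))[0])
            row = g[:, j].copy()
            # state = number of opposite-species alleles; missing = -1
            prow = panel.primary[(panel.primary["scaffold"] == s) &
                                 (panel.primary["position"] == p)]
            opp_hom = _opposite_hom_code(prow, species)[0]
            state = np.full(len(ids), -1, dtype=np.int8)
            state[row == 1] = 1
            state[row == opp_hom] = 2
            state[(row >= 0) & (row != 1) & (row != opp_hom)] = 0
            opp_state[(s, p)] = state

        # complete association = identical states on co-called individuals
        # with at least one shared carrier; grouped by union-find so an
        # introgressed chunk split by stray missing calls still coheres
        locus_list = list(opp_state)
        parent = list(range(len(locus_list)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(locus_list)):
            for j in range(i + 1, len(locus_list)):
                si, sj = opp_state[locus_list[i]], opp_state[locus_list[j]]
                co = (si >= 0) & (sj >= 0)
                shared = int(((si > 0) & (sj > 0) & co).sum())
                mism = int((si[co] != sj[co]).sum())
                if shared and mism == 0:
                    parent[find(i)] = find(j)
                elif shared and mism:
                    partial.append({"locus_a": locus_list[i],
                                    "locus_b": locus_list[j],
                                    "shared_carriers": shared,
                                    "mismatches": mism})

        components: dict = {}
        for i, locus in enumerate(locus_list):
            components.setdefault(find(i), []).append(locus)

        for members in components.values():
            scafs = {s for s, _ in members}
            if len(scafs) < 2:
                continue
            # consensus state per individual: first called state over loci
            state = np.full(len(ids), -1, dtype=np.int8)
            for locus in members:
                s = opp_state[locus]
                fill = (state < 0) & (s >= 0)
                state[fill] = s[fill]
            n_car = int((state > 0).sum())
            if n_car < min_carriers:
                continue
            carriers = pd.DataFrame({
                "sample_id": [ids[i] for i in np.flatnonzero(state > 0)],
                "state": ["het" if state[i] == 1 else "hom"
                          for i in np.flatnonzero(state > 0)]})
            # secondary-panel confirmation on member scaffolds
            support = []
            sec = panel.secondary[
                panel.secondary["scaffold"].isin(scafs)]
            for _, r in sec.iterrows():
                locus = (r["scaffold"], int(r["position"]))
                if locus in members:
                    continue
                j = np.flatnonzero((matrix.scaffold == locus[0]) &
                                   (matrix.position == locus[1]))
                if len(j) == 0:
                    continue
                row = g[:, int(j[0])]
                opp_hom = 2 if r["rivale_is_alt"] == (species == "urbanum") \
                    else 0
                st = np.full(len(ids), -1, dtype=np.int8)
                st[row == 1] = 1
                st[row == opp_hom] = 2
                st[(row >= 0) & (row != 1) & (row != opp_hom)] = 0
                co = (st >= 0) & (state >= 0)
                if co.any() and (st[co] == state[co]).all() \
                        and ((st > 0) & (state > 0) & co).any():
                    support.append(locus)
            groups.append(CosegregationGroup(
                loci=sorted(members), scaffolds=scafs, carriers=carriers,
                recipient=species, association="complete",
                n_carriers=n_car, secondary_support=sorted(support)))
    return CosegregationScan(groups=groups, partial=partial)
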