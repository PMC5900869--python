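"""Per-SNP and per-scaffold population-genetic summary statistics.

Covers the polymorphism-type classification of SNPs within and between the
two species, per-SNP observed/expected heterozygosity and F_IS, the paralog
scaffold filter based on excess heterozygosity, per-individual diversity,
Hudson-type pairwise F_ST, between-group dxy per scaffold, the f3 admixture
test with a scaffold-level bootstrap, and a composition (chi-square) test
comparing a subset of SNPs against the full classification.

All allele-frequency estimates use called alleles only; missing genotypes
are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import GenotypeMatrix

POLYMORPHISM_CATEGORIES = ("alternately_fixed", "poly_r_only", "poly_u_only",
                           "shared_poly", "monomorphic")


# ---------------------------------------------------------------------------
# per-SNP allele counts and heterozygosity
# ---------------------------------------------------------------------------

def _called(g: np.ndarray) -> np.ndarray:
    return g >= 0


def allele_frequencies(matrix: GenotypeMatrix, sample_ids,
                       min_called: int = 0):
    """ALT-allele frequency and called-sample count per site for a group.

    Sites with fewer than ``min_called`` called individuals get frequency
    NaN so callers can mask them.
    """
    g = matrix.rows(sample_ids)
    called = _called(g)
    n = called.sum(axis=0)
    alt = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, alt / (2.0 * n), np.nan)
    if min_called:
        freq = np.where(n >= min_called, freq, np.nan)
    return freq, n


def snp_stats(matrix: GenotypeMatrix, sample_ids) -> pd.DataFrame:
    """Observed heterozygosity, He = 2p(1-p) and F_IS = 1 - Ho/He per SNP."""
    if len(sample_ids) == 0:
        raise ValueError("group must be non-empty")
    g = matrix.rows(sample_ids)
    called = _called(g)
    n = called.sum(axis=0)
    alt = np.where(called, g, 0).sum(axis=0)
    het = ((g == 1) & called).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        ho = np.where(n > 0, het / n, np.nan)
        he = 2.0 * p * (1.0 - p)
        fis = np.where(he > 0, 1.0 - ho / he, np.nan)
    return pd.DataFrame({"scaffold": matrix.scaffold,
                         "position": matrix.position,
                         "p": p, "Ho": ho, "He": he, "F_IS": fis,
                         "n_called": n})


def individual_pi(matrix: GenotypeMatrix, sample_id):
    """Fraction of called sites that are heterozygous, with binomial SE."""
    g = matrix.genotypes[matrix.sample_index(sample_id)]
    called = _called(g)
    n = int(called.sum())
    if n == 0:
        return np.nan, np.nan, 0
    pi = float((g[called] == 1).mean())
    se = float(np.sqrt(pi * (1.0 - pi) / n))
    return pi, se, n


# ---------------------------------------------------------------------------
# polymorphism classification
# ---------------------------------------------------------------------------

@dataclass
class PolymorphismTable:
    per_snp: pd.DataFrame           # scaffold, position, category
    counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.counts:
            vc = self.per_snp["category"].value_counts()
            self.counts = {c: int(vc.get(c, 0))
                           for c in POLYMORPHISM_CATEGORIES}
            self.counts["uncallable"] = int(vc.get("uncallable", 0))

    @classmethod
    def from_counts(cls, counts: dict) -> "PolymorphismTable":
        return cls(per_snp=pd.DataFrame(columns=["category"]),
                   counts=dict(counts))

    @property
    def total(self) -> int:
        return sum(v for k, v in self.counts.items() if k != "uncallable")

    def proportions(self) -> dict:
        tot = self.total
        return {k: (v / tot if tot else np.nan)
                for k, v in self.counts.items() if k != "uncallable"}

    def percent(self, category: str, ndigits: int = 0) -> float:
        return round(100.0 * self.proportions()[category], ndigits)


def classify_polymorphism(matrix: GenotypeMatrix, group_r,
                          group_u) -> PolymorphismTable:
    """Classify every SNP by which species segregate which alleles.

    Categories follow the within/between-species polymorphism table:
    alternately fixed, polymorphic in one species with one allele fixed in
    the other, shared polymorphism, or monomorphic overall.  SNPs with no
    called allele in a group are reported as "uncallable".
    """
    if len(group_r) == 0 or len(group_u) == 0:
        raise ValueError("both groups must be non-empty")
    cats = np.empty(matrix.n_sites, dtype=object)
    seen = []
    for ids in (group_r, group_u):
        g = matrix.rows(ids)
        called = _called(g)
        n = called.sum(axis=0)
        alt = np.where(called, g, 0).sum(axis=0)
        has_ref = alt < 2 * n
        has_alt = alt > 0
        seen.append((n > 0, has_ref & (n > 0), has_alt))
    (ok_r, ref_r, alt_r), (ok_u, ref_u, alt_u) = seen
    poly_r = ref_r & alt_r
    poly_u = ref_u & alt_u
    cats[:] = "monomorphic"
    cats[poly_r & ~poly_u] = "poly_r_only"
    cats[poly_u & ~poly_r] = "poly_u_only"
    cats[poly_r & poly_u] = "shared_poly"
    fixed_diff = (~poly_r & ~poly_u & ok_r & ok_u &
                  (alt_r != alt_u))  # each fixed, for different alleles
    cats[fixed_diff] = "alternately_fixed"
    cats[~ok_r | ~ok_u] = "uncallable"
    per_snp = pd.DataFrame({"scaffold": matrix.scaffold,
                            "position": matrix.position,
                            "category": cats})
    return PolymorphismTable(per_snp)


# ---------------------------------------------------------------------------
# paralog filter
# ---------------------------------------------------------------------------

def paralog_filter(matrix: GenotypeMatrix, group_r, group_u,
                   ho_max: float = 0.5, fis_min: float = 0.0):
    """Exclude scaffolds with any SNP showing the pooled-paralog signature.

    A scaffold is dropped when any of its SNPs, in either species, shows
    observed heterozygosity strictly above ``ho_max`` or F_IS strictly
    below ``fis_min`` (excess heterozygosity is the expected artefact of
    reads from duplicated regions mapping to one location).  Returns the
    retained scaffold set and a report of excluded scaffolds with their
    triggering SNPs.
    """
    reports = []
    for label, ids in (("rivale", group_r), ("urbanum", group_u)):
        st = snp_stats(matrix, ids)
        bad = (st["Ho"] > ho_max) | (st["F_IS"] < fis_min)
        bad = bad.fillna(False)
        sub = st.loc[bad, ["scaffold", "position", "Ho", "F_IS"]].copy()
        sub["species"] = label
        reports.append(sub)
    report = pd.concat(reports, ignore_index=True)
    excluded = set(report["scaffold"])
    retained = set(matrix.scaffold) - excluded
    return retained, report


# ---------------------------------------------------------------------------
# F_ST (Hudson, ratio of averages)
# ---------------------------------------------------------------------------

def _hudson_components(p1, n1, p2, n2):
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
           - p2 * (1 - p2) / np.maximum(n2 - 1, 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def fst(matrix: GenotypeMatrix, groups: dict) -> pd.DataFrame:
    """Pairwise Hudson F_ST averaged across loci (ratio of averages).

    ``groups`` maps group name -> sample id list.  Loci where either group
    of a pair has fewer than two called individuals, or where the pair is
    jointly monomorphic, do not contribute to that pair.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    freqs = {}
    for name, ids in groups.items():
        f, n = allele_frequencies(matrix, ids)
        freqs[name] = (f, n)
    names = list(groups)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            p1, n1 = freqs[a]
            p2, n2 = freqs[b]
            ok = (n1 >= 2) & (n2 >= 2) & ~np.isnan(p1) & ~np.isnan(p2)
            num, den = _hudson_components(p1[ok], n1[ok], p2[ok], n2[ok])
            use = den > 0
            val = num[use].sum() / den[use].sum() if use.any() else np.nan
            out.loc[a, b] = out.loc[b, a] = val
    return out


# ---------------------------------------------------------------------------
# dxy
# ---------------------------------------------------------------------------

@dataclass
class DxyResult:
    per_scaffold: pd.DataFrame   # scaffold, dxy, n_snps, n_sites
    mean: float
    se: float
    n_scaffolds: int
    skipped: list = field(default_factory=list)


def dxy(matrix: GenotypeMatrix, group_x, group_y,
        sites_per_scaffold: dict, min_called: int = 12) -> DxyResult:
    """Between-group divergence per scaffold.

    dxy = sum over qualifying SNPs of PX(1-PY) + (1-PX)PY, divided by the
    number of genotyped sites on the scaffold's analysed radtags (supplied
    in ``sites_per_scaffold``).  Only SNPs called in at least ``min_called``
    individuals in both groups qualify.  Because unobserved (monomorphic)
    radtags cannot enter the denominator, the result is a relative rather
    than absolute divergence measure.
    """
    fx, _ = allele_frequencies(matrix, group_x, min_called)
    fy, _ = allele_frequencies(matrix, group_y, min_called)
    ok = ~np.isnan(fx) & ~np.isnan(fy)
    term = np.where(ok, fx * (1 - fy) + (1 - fx) * fy, 0.0)
    df = pd.DataFrame({"scaffold": matrix.scaffold, "term": term, "ok": ok})
    per = df.groupby("scaffold", sort=True).agg(
        total=("term", "sum"), n_snps=("ok", "sum")).reset_index()
    skipped = []
    rows = []
    for _, row in per.iterrows():
        scaf = row["scaffold"]
        n_sites = sites_per_scaffold.get(scaf, 0)
        if n_sites <= 0 or row["n_snps"] == 0:
            skipped.append(scaf)
            continue
        rows.append((scaf, row["total"] / n_sites, int(row["n_snps"]),
                     int(n_sites)))
    per_scaffold = pd.DataFrame(
        rows, columns=["scaffold", "dxy", "n_snps", "n_sites"])
    vals = per_scaffold["dxy"].to_numpy()
    if len(vals) == 0:
        return DxyResult(per_scaffold, np.nan, np.nan, 0, skipped)
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
    return DxyResult(per_scaffold, mean, se, len(vals), skipped)


# ---------------------------------------------------------------------------
# f3 with scaffold bootstrap
# ---------------------------------------------------------------------------

@dataclass
class F3Result:
    f3: float
    n_snps: int
    n_scaffolds: int
    n_boot: int
    ci_lower: float
    ci_upper: float
    seed: int
    significant_introgression: bool
    bootstrap_values: np.ndarray = None


def f3_test(freq_a, freq_b, freq_c, scaffolds, n_boot: int = 2000,
            seed: int = 0) -> F3Result:
    """f3 = mean over SNPs of (c-a)(c-b); negative values signal admixture
    in the target population c.

    The 95% CI comes from resampling whole scaffolds with replacement
    (SNPs on one scaffold are linked, so the scaffold is the exchangeable
    unit); "significant introgression" means the percentile CI lies
    entirely below zero.  The statistic is the plain mean of products,
    without a finite-sample heterozygosity correction.
    """
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    c = np.asarray(freq_c, dtype=float)
    scaffolds = np.asarray(scaffolds)
    ok = ~(np.isnan(a) | np.isnan(b) | np.isnan(c))
    a, b, c, scaffolds = a[ok], b[ok], c[ok], scaffolds[ok]
    if len(a) == 0:
        raise ValueError("no SNPs with all three frequencies defined")
    prod = (c - a) * (c - b)
    f3 = float(prod.mean())

    uniq, inv = np.unique(scaffolds, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("scaffold bootstrap needs at least 2 scaffolds")
    sums = np.bincount(inv, weights=prod)
    counts = np.bincount(inv).astype(float)

    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(uniq), size=(n_boot, len(uniq)))
    boot = sums[picks].sum(axis=1) / counts[picks].sum(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return F3Result(f3=f3, n_snps=len(a), n_scaffolds=len(uniq),
                    n_boot=n_boot, ci_lower=float(lo), ci_upper=float(hi),
                    seed=seed, significant_introgression=bool(hi < 0.0),
                    bootstrap_values=boot)


# ---------------------------------------------------------------------------
# composition test
# ---------------------------------------------------------------------------

def composition_test(subset: PolymorphismTable, total: PolymorphismTable,
                     categories=None, n_sim: int = 10000, seed: int = 0):
    """Chi-square test that a subset of SNPs has the same category mix as
    the full classification; Monte-Carlo null when expected counts are < 5.

    Returns dict with statistic, df, p_value and method.
    """
    if categories is None:
        categories = [c for c in POLYMORPHISM_CATEGORIES
                      if c != "monomorphic"]
    obs = np.array([subset.counts.get(c, 0) for c in categories],
                   dtype=float)
    tot = np.array([total.counts.get(c, 0) for c in categories],
                   dtype=float)
    if obs.sum() == 0:
        raise ValueError("subset is empty")
    if tot.sum() == 0:
        raise ValueError("total table is empty")
    p_exp = tot / tot.sum()
    keep = p_exp > 0
    obs, p_exp = obs[keep], p_exp[keep]
    n = obs.sum()
    expected = n * p_exp
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    if (expected >= 5).all():
        p = float(sps.chi2.sf(stat, df))
        method = "chi2"
    else:
        rng = np.random.default_rng(seed)
        sims = rng.multinomial(int(n), p_exp, size=n_sim)
        sim_stat = (((sims - expected) ** 2) / expected).sum(axis=1)
        p = float((1 + (sim_stat >= stat - 1e-12).sum()) / (1 + n_sim))
        method = "monte_carlo"
    return {"statistic": stat, "df": df, "p_value": p, "method": method,
            "n_subset": int(n)}
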