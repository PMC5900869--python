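"""Genotype matrix container and VCF / metadata I/O.

The central data structure couples an individuals x sites matrix of diploid
biallelic genotype codes with per-site scaffold/position metadata and a
per-sample metadata table (species, population, allopatric/sympatric zone).

Genotype codes count copies of the ALT allele: 0, 1, 2; ``-1`` marks a
missing call (``./.``) and ``-2`` a call involving a third allele at a
multiallelic record (excluded from every statistic, but tallied separately
where the analysis reports exclusions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1
THIRD_ALLELE = -2

METADATA_COLUMNS = ("sample_id", "species", "population", "zone")


@dataclass
class GenotypeMatrix:
    genotypes: np.ndarray            # (n_samples, n_sites) int8
    scaffold: np.ndarray             # (n_sites,) str
    position: np.ndarray             # (n_sites,) int, 1-based
    ref: np.ndarray                  # (n_sites,) str
    alt: np.ndarray                  # (n_sites,) str
    samples: pd.DataFrame            # columns METADATA_COLUMNS
    multiallelic: np.ndarray = None  # (n_sites,) bool flags

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.scaffold = np.asarray(self.scaffold)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        if self.multiallelic is None:
            self.multiallelic = np.zeros(self.n_sites, dtype=bool)
        self.samples = self.samples.reset_index(drop=True)
        if self.genotypes.shape != (len(self.samples), len(self.scaffold)):
            raise ValueError("genotype matrix shape does not match metadata")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sample_ids(self) -> list:
        return list(self.samples["sample_id"])

    def sample_index(self, sample_id) -> int:
        idx = self.samples.index[self.samples["sample_id"] == sample_id]
        if len(idx) != 1:
            raise KeyError(f"sample {sample_id!r} not found")
        return int(idx[0])

    def group_ids(self, species=None, zone=None, population=None) -> list:
        sel = pd.Series(True, index=self.samples.index)
        if species is not None:
            sel &= self.samples["species"] == species
        if zone is not None:
            sel &= self.samples["zone"] == zone
        if population is not None:
            sel &= self.samples["population"] == population
        return list(self.samples.loc[sel, "sample_id"])

    def rows(self, sample_ids) -> np.ndarray:
        idx = [self.sample_index(s) for s in sample_ids]
        return self.genotypes[idx]

    def take_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(self.genotypes[idx], self.scaffold,
                              self.position, self.ref, self.alt,
                              self.samples.iloc[idx],
                              self.multiallelic)

    def take_sites(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(self.genotypes[:, mask], self.scaffold[mask],
                              self.position[mask], self.ref[mask],
                              self.alt[mask], self.samples,
                              self.multiallelic[mask])

    def site_key(self) -> pd.DataFrame:
        return pd.DataFrame({"scaffold": self.scaffold,
                             "position": self.position})

    # -- I/O ----------------------------------------------------------------
    def to_vcf(self, path) -> None:
        """Write one biallelic record per site (GT only, ``./.`` = missing)."""
        path = Path(path)
        order = np.lexsort((self.position, self.scaffold))
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
            for contig in pd.unique(self.scaffold[order]):
                fh.write(f"##contig=<ID={contig}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(str(s) for s in self.sample_ids) + "\n")
            gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./.",
                      THIRD_ALLELE: "./."}
            for j in order:
                cols = [str(self.scaffold[j]), str(self.position[j]), ".",
                        str(self.ref[j]), str(self.alt[j]), ".", "PASS", ".",
                        "GT"]
                cols += [gt_str[int(g)] for g in self.genotypes[:, j]]
                fh.write("\t".join(cols) + "\n")

    def write_metadata(self, path) -> None:
        self.samples.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file {path} lacks columns {missing}")
    return meta


def read_genotypes(vcf_path, metadata_path) -> GenotypeMatrix:
    """Load a VCF plus sample-metadata TSV into a :class:`GenotypeMatrix`.

    Multiallelic records are retained with a per-site flag; genotypes that
    involve an allele index above 1 are stored as :data:`THIRD_ALLELE`.
    Every VCF sample must appear in the metadata table.
    """
    from cyvcf2 import VCF

    meta = read_metadata(metadata_path)
    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    known = set(meta["sample_id"])
    offenders = [s for s in vcf_samples if s not in known]
    if offenders:
        raise ValueError(
            f"samples in VCF but absent from metadata: {offenders}")

    scaff, pos, ref, alt, multi, rows = [], [], [], [], [], []
    for v in vcf:
        scaff.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0] if v.ALT else ".")
        multi.append(len(v.ALT) > 1)
        g = np.array([row[:2] for row in v.genotypes], dtype=np.int64)
        code = g.sum(axis=1).astype(np.int8)
        code[(g >= 2).any(axis=1)] = THIRD_ALLELE
        code[(g < 0).any(axis=1)] = MISSING
        rows.append(code)
    if not rows:
        raise ValueError(f"no records in {vcf_path}")

    meta = (meta.set_index("sample_id").loc[vcf_samples]
            .reset_index())
    return GenotypeMatrix(
        genotypes=np.array(rows, dtype=np.int8).T,
        scaffold=np.array(scaff), position=np.array(pos),
        ref=np.array(ref), alt=np.array(alt), samples=meta,
        multiallelic=np.array(multi))
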