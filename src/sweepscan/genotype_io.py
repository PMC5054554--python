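"""Phased genotype I/O and the shared in-memory haplotype representation.

Every statistic in this package operates on a :class:`HaplotypeSet`: a
``2N x M`` binary matrix of phased haplotypes (rows are haplotypes, two
consecutive rows per diploid sample; columns are biallelic SNPs in map
order) together with a SNP map of genomic coordinates.  Input must be
fully phased and complete — missing genotypes are a pre-phasing concern
handled by :mod:`sweepscan.qc` on a separate diploid genotype table.

Coordinates are 1-based (VCF convention) throughout; BED annotations are
converted on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeSet",
    "read_phased_vcf",
    "write_phased_vcf",
    "allele_counts",
    "read_bed_annotation",
    "write_bed_annotation",
]

#: Required columns of a SNP map, in order.
SNP_MAP_COLUMNS = ("id", "chrom", "pos", "allele0", "allele1")


@dataclass
class HaplotypeSet:
    """Phased haplotypes for one population.

    Parameters
    ----------
    haps
        ``(2N, M)`` array of allele indices in {0, 1}.  Row ``2i`` and
        ``2i + 1`` are the two haplotypes of sample ``i``.
    snp_map
        DataFrame with columns ``id, chrom, pos, allele0, allele1``;
        ``pos`` is 1-based and strictly increasing within a chromosome.
    sample_ids
        N sample identifiers.
    pop_label
        Free-text population name.
    """

    haps: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: list[str]
    pop_label: str = ""

    def __post_init__(self) -> None:
        self.haps = np.ascontiguousarray(np.asarray(self.haps, dtype=np.int8))
        if self.haps.ndim != 2:
            raise ValueError("hap matrix must be 2-D")
        if self.haps.shape[0] % 2 != 0:
            raise ValueError("hap matrix must have an even number of rows")
        if self.haps.shape[0] != 2 * len(self.sample_ids):
            raise ValueError(
                f"{self.haps.shape[0]} haplotype rows but {len(self.sample_ids)} samples"
            )
        vals = np.unique(self.haps)
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("hap matrix entries must be 0/1 (phased, complete)")
        self.snp_map = self.snp_map.reset_index(drop=True)
        missing = [c for c in SNP_MAP_COLUMNS if c not in self.snp_map.columns]
        if missing:
            raise ValueError(f"snp_map lacks columns {missing}")
        if len(self.snp_map) != self.haps.shape[1]:
            raise ValueError("snp_map length does not match hap matrix width")
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise ValueError("bp positions must be strictly increasing per chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haps.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haps.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return self.snp_map["pos"].to_numpy()

    def take_snps(self, index: np.ndarray) -> "HaplotypeSet":
        """Subset to the SNP columns in ``index`` (kept in given order)."""
        return HaplotypeSet(
            haps=self.haps[:, index],
            snp_map=self.snp_map.iloc[np.asarray(index)].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
            pop_label=self.pop_label,
        )


def allele_counts(hapset: HaplotypeSet) -> pd.DataFrame:
    """Per-SNP allele counts and minor allele frequency.

    Returns a DataFrame with columns ``n0`` (count of allele 0), ``n1``
    (count of allele 1) and ``maf`` = min(n0, n1) / 2N, aligned with the
    SNP map.
    """
    n1 = hapset.haps.sum(axis=0).astype(np.int64)
    n0 = hapset.n_haplotypes - n1
    maf = np.minimum(n0, n1) / float(hapset.n_haplotypes)
    return pd.DataFrame({"id": hapset.snp_map["id"], "n0": n0, "n1": n1, "maf": maf})


# ---------------------------------------------------------------------------
# VCF


def read_phased_vcf(path: str | os.PathLike, pop_label: str = "") -> HaplotypeSet:
    """Read a phased, biallelic VCF into a :class:`HaplotypeSet`.

    Rejects unphased genotypes (``/`` separator) and multi-allelic
    records, reporting the offending locus.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    sample_ids = list(vcf.samples)
    rows: list[np.ndarray] = []
    ids, chroms, poss, a0s, a1s = [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"multi-allelic record at {v.CHROM}:{v.POS}")
        gts = v.genotypes  # [a, b, phased] per sample
        col = np.empty(2 * len(sample_ids), dtype=np.int8)
        for i, g in enumerate(gts):
            if len(g) < 3 or not g[2]:
                raise ValueError(f"unphased genotype at {v.CHROM}:{v.POS} sample {sample_ids[i]}")
            if g[0] < 0 or g[1] < 0:
                raise ValueError(f"missing genotype at {v.CHROM}:{v.POS} sample {sample_ids[i]}")
            col[2 * i] = g[0]
            col[2 * i + 1] = g[1]
        rows.append(col)
        ids.append(v.ID if v.ID is not None else f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        a0s.append(v.REF)
        a1s.append(v.ALT[0])
    vcf.close()
    haps = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((2 * len(sample_ids), 0), dtype=np.int8)
    )
    snp_map = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "allele0": a0s, "allele1": a1s}
    )
    return HaplotypeSet(haps=haps, snp_map=snp_map, sample_ids=sample_ids, pop_label=pop_label)


def write_phased_vcf(hapset: HaplotypeSet, path: str | os.PathLike) -> None:
    """Write a :class:`HaplotypeSet` as a phased VCF 4.2 file."""
    sm = hapset.snp_map
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, grp in sm.groupby("chrom", sort=False):
            length = int(grp["pos"].max()) + 1 if len(grp) else 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(hapset.sample_ids)
            + "\n"
        )
        haps = hapset.haps
        for j in range(hapset.n_snps):
            rec = sm.iloc[j]
            gts = "\t".join(
                f"{haps[2 * i, j]}|{haps[2 * i + 1, j]}" for i in range(hapset.n_samples)
            )
            fh.write(
                f"{rec['chrom']}\t{rec['pos']}\t{rec['id']}\t{rec['allele0']}\t"
                f"{rec['allele1']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# BED annotations (feature classes for snpclass)


def read_bed_annotation(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED annotation (0-based half-open) into 1-based inclusive
    ``start``/``end`` columns plus ``chrom``, ``name`` and optional
    ``gene_id`` (column 5 if present)."""
    chroms, starts, ends, names, genes = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"malformed annotation line {lineno}: {line!r}")
            try:
                s0, e0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed annotation line {lineno}: {line!r}") from exc
            chroms.append(parts[0])
            starts.append(s0 + 1)  # to 1-based inclusive
            ends.append(e0)
            names.append(parts[3])
            genes.append(parts[4] if len(parts) > 4 else "")
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "name": names, "gene_id": genes}
    )


def write_bed_annotation(ann: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write 1-based inclusive feature intervals back out as BED."""
    with open(path, "w") as fh:
        for _, r in ann.iterrows():
            gene = r["gene_id"] if "gene_id" in ann.columns else ""
            fh.write(f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t{r['name']}\t{gene}\n")
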