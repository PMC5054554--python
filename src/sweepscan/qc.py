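"""Quality control and relatedness filtering on diploid genotype tables.

Operates on pre-phasing genotype data that may contain missing calls:
an N x M matrix of minor-allele dosages in {0, 1, 2} with -1 for
missing.  Filters (in order): per-individual missingness, per-SNP MAF
and Hardy–Weinberg exact test, then LD pruning and PLINK-style
method-of-moments pi-hat for the relatedness filter.  Default
thresholds: missingness 0.05, MAF 0.05, HWE P < 1e-6, indep-pairwise
50/5/0.2, pi-hat 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import HaplotypeSet

__all__ = [
    "GenotypeTable",
    "QcThresholds",
    "hwe_exact_p",
    "filter_individuals_missing",
    "filter_snps",
    "ld_prune",
    "pihat_matrix",
    "remove_related",
    "run_qc",
]

MISSING = -1


@dataclass
class GenotypeTable:
    """Diploid genotypes: dosage of allele1 in {0,1,2}, -1 = missing."""

    geno: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        if self.geno.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match sample_ids")
        if self.geno.shape[1] != len(self.snp_map):
            raise ValueError("column count does not match snp_map")
        bad = ~np.isin(self.geno, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype entries must be in {-1, 0, 1, 2}")
        self.snp_map = self.snp_map.reset_index(drop=True)

    @classmethod
    def from_haplotypes(cls, hapset: HaplotypeSet) -> "GenotypeTable":
        geno = hapset.haps[0::2] + hapset.haps[1::2]
        return cls(geno.astype(np.int8), hapset.snp_map.copy(), list(hapset.sample_ids))

    @property
    def n_samples(self) -> int:
        return self.geno.shape[0]

    @property
    def n_snps(self) -> int:
        return self.geno.shape[1]

    def take_samples(self, idx: np.ndarray) -> "GenotypeTable":
        idx = np.asarray(idx)
        return GenotypeTable(
            self.geno[idx], self.snp_map.copy(), [self.sample_ids[i] for i in idx]
        )

    def take_snps(self, idx: np.ndarray) -> "GenotypeTable":
        idx = np.asarray(idx)
        return GenotypeTable(
            self.geno[:, idx], self.snp_map.iloc[idx].reset_index(drop=True), list(self.sample_ids)
        )


@dataclass
class QcThresholds:
    max_ind_missing: float = 0.05
    min_maf: float = 0.05
    hwe_alpha: float = 1e-6
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.2
    max_pihat: float = 0.2

    def validate(self) -> None:
        if not (0 <= self.max_ind_missing <= 1 and 0 <= self.min_maf <= 0.5):
            raise ValueError("missingness/MAF thresholds out of range")
        if not (0 < self.hwe_alpha < 1):
            raise ValueError("hwe_alpha out of range")
        if self.prune_window < 2 or self.prune_step < 1 or not (0 < self.prune_r2 <= 1):
            raise ValueError("pruning parameters out of range")
        if not (0 < self.max_pihat <= 1):
            raise ValueError("max_pihat out of range")


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy–Weinberg test P value (two-sided, no mid-P).

    Sums the probabilities of all heterozygote counts (given the allele
    counts) whose conditional probability does not exceed that of the
    observed count.  Log-factorial arithmetic keeps it stable for large
    samples.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    n_a = 2 * n_aa + n_ab  # rarer or not, symmetric below
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = (max(n_a, n_b) - hets) // 2
    # log P(het = h | allele counts) up to a common constant
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.nonzero(hets == n_ab)[0][0]]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def filter_individuals_missing(
    table: GenotypeTable, max_ind_missing: float = 0.05
) -> tuple[GenotypeTable, list[str]]:
    """Drop individuals whose missing-genotype fraction exceeds the
    threshold; returns the filtered table and the removed ids."""
    if table.n_snps == 0:
        return table, []
    frac = (table.geno == MISSING).mean(axis=1)
    keep = np.nonzero(frac <= max_ind_missing)[0]
    removed = [table.sample_ids[i] for i in np.nonzero(frac > max_ind_missing)[0]]
    return table.take_samples(keep), removed


def snp_maf(table: GenotypeTable) -> np.ndarray:
    """Per-SNP minor allele frequency from non-missing genotypes."""
    geno = np.ma.masked_equal(table.geno, MISSING)
    n_called = (~geno.mask).sum(axis=0) if geno.mask is not np.ma.nomask else np.full(
        table.n_snps, table.n_samples
    )
    n_called = np.asarray(n_called)
    dose = np.asarray(geno.sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n_called > 0, dose / (2.0 * n_called), 0.0)
    return np.minimum(p1, 1.0 - p1)


def filter_snps(
    table: GenotypeTable,
    min_maf: float = 0.05,
    hwe_alpha: float = 1e-6,
    apply_maf: bool = True,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """MAF and HWE SNP filters.

    ``apply_maf=False`` disables the MAF filter (used for the
    between-population tests, which keep low-MAF loci).  Returns the
    filtered table and a log of removed SNPs with reasons.
    """
    maf = snp_maf(table)
    keep = np.ones(table.n_snps, dtype=bool)
    reasons: dict[int, str] = {}
    if apply_maf:
        low = maf < min_maf
        keep &= ~low
        for j in np.nonzero(low)[0]:
            reasons[j] = "maf"
    for j in range(table.n_snps):
        if not keep[j]:
            continue
        col = table.geno[:, j]
        col = col[col != MISSING]
        p = hwe_exact_p(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        if p < hwe_alpha:
            keep[j] = False
            reasons[j] = "hwe"
    log = pd.DataFrame(
        {
            "id": [table.snp_map["id"].iloc[j] for j in sorted(reasons)],
            "reason": [reasons[j] for j in sorted(reasons)],
        }
    )
    return table.take_snps(np.nonzero(keep)[0]), log


def _geno_r2(geno: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of genotype dosages (pairwise-complete)."""
    a, b = geno[:, i], geno[:, j]
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    a = a[ok].astype(float)
    b = b[ok].astype(float)
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        return 0.0
    c = ((a - a.mean()) * (b - b.mean())).mean()
    return float(c * c / (va * vb))


def ld_prune(
    table: GenotypeTable,
    prune_window: int = 50,
    prune_step: int = 5,
    prune_r2: float = 0.2,
) -> np.ndarray:
    """Sliding-window LD pruning (indep-pairwise style).

    Within each window of ``prune_window`` SNPs (advanced by
    ``prune_step``), repeatedly removes the later SNP of any retained
    pair with genotype r² above ``prune_r2``.  Returns the retained SNP
    indices (deterministic: the earlier SNP of a conflicting pair wins).
    """
    m = table.n_snps
    keep = np.ones(m, dtype=bool)
    start = 0
    while True:
        end = min(start + prune_window, m)
        idx = [j for j in range(start, end) if keep[j]]
        for a in range(len(idx)):
            if not keep[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if not keep[idx[b]]:
                    continue
                if _geno_r2(table.geno, idx[a], idx[b]) > prune_r2:
                    keep[idx[b]] = False
        if end >= m:
            break
        start += prune_step
    return np.nonzero(keep)[0]


def pihat_matrix(table: GenotypeTable) -> np.ndarray:
    """Pairwise pi-hat = P(IBD=1)/2 + P(IBD=2), method of moments.

    Uses expected identity-by-state probabilities given sample allele
    frequencies (PLINK-style, without small-sample bias corrections);
    estimates are clamped to [0, 1].  Assumes a pruned, near-independent
    SNP set.
    """
    n = table.n_samples
    if n < 2:
        return np.zeros((n, n))
    geno = table.geno.astype(float)
    geno[table.geno == MISSING] = np.nan
    maf_p = np.nanmean(geno, axis=0) / 2.0  # freq of allele1
    p, q = maf_p, 1.0 - maf_p
    ok = (p > 0) & (p < 1)
    p, q = p[ok], q[ok]
    g = geno[:, ok]

    # expected IBS-state probabilities per SNP given IBD state
    e0_ibs0 = 2 * p**2 * q**2
    e0_ibs1 = 4 * p**3 * q + 4 * p * q**3
    e0_ibs2 = p**4 + q**4 + 4 * p**2 * q**2
    e1_ibs1 = 2 * p**2 * q + 2 * p * q**2
    e1_ibs2 = p**3 + q**3 + p**2 * q + p * q**2

    pihat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = g[i], g[j]
            okij = ~np.isnan(a) & ~np.isnan(b)
            if okij.sum() == 0:
                continue
            d = np.abs(a[okij] - b[okij])
            ibs0 = float((d == 2).sum())
            ibs1 = float((d == 1).sum())
            ibs2 = float((d == 0).sum())
            E0_0 = e0_ibs0[okij].sum()
            E0_1 = e0_ibs1[okij].sum()
            E0_2 = e0_ibs2[okij].sum()
            E1_1 = e1_ibs1[okij].sum()
            E1_2 = e1_ibs2[okij].sum()
            P0 = ibs0 / E0_0 if E0_0 > 0 else 0.0
            P1 = (ibs1 - P0 * E0_1) / E1_1 if E1_1 > 0 else 0.0
            n_used = okij.sum()
            P2 = (ibs2 - P0 * E0_2 - P1 * E1_2) / n_used
            P0, P1, P2 = (min(max(x, 0.0), 1.0) for x in (P0, P1, P2))
            s = P0 + P1 + P2
            if s > 0:
                P0, P1, P2 = P0 / s, P1 / s, P2 / s
            ph = P1 / 2.0 + P2
            pihat[i, j] = pihat[j, i] = min(max(ph, 0.0), 1.0)
    return pihat


def remove_related(
    pihat: np.ndarray, sample_ids: list[str], max_pihat: float = 0.2
) -> list[str]:
    """Greedy relatedness filter: repeatedly drop the individual in the
    most over-threshold pairs (ties: drop the later sample id) until no
    pair exceeds ``max_pihat``.  Returns the retained ids in order."""
    n = len(sample_ids)
    active = np.ones(n, dtype=bool)
    over = pihat > max_pihat
    np.fill_diagonal(over, False)
    while True:
        counts = (over & active[None, :] & active[:, None]).sum(axis=1)
        counts[~active] = 0
        worst = counts.max() if n else 0
        if worst == 0:
            break
        cands = np.nonzero(counts == worst)[0]
        active[cands[-1]] = False  # later index = later sample id
    return [sample_ids[i] for i in range(n) if active[i]]


def run_qc(
    table: GenotypeTable,
    thresholds: QcThresholds | None = None,
    apply_maf: bool = True,
) -> tuple[GenotypeTable, dict]:
    """Full QC chain: individual missingness → SNP MAF/HWE filters →
    LD-prune (for relatedness only) → pi-hat removal.

    Returns the filtered table (all post-filter SNPs, related and
    high-missing individuals removed) and a log dict.
    """
    th = thresholds or QcThresholds()
    th.validate()
    table1, removed_missing = filter_individuals_missing(table, th.max_ind_missing)
    table2, snp_log = filter_snps(table1, th.min_maf, th.hwe_alpha, apply_maf=apply_maf)
    pruned_idx = ld_prune(table2, th.prune_window, th.prune_step, th.prune_r2)
    pruned = table2.take_snps(pruned_idx)
    ph = pihat_matrix(pruned)
    kept_ids = remove_related(ph, table2.sample_ids, th.max_pihat)
    removed_related = [s for s in table2.sample_ids if s not in set(kept_ids)]
    keep_rows = [i for i, s in enumerate(table2.sample_ids) if s in set(kept_ids)]
    out = table2.take_samples(np.asarray(keep_rows, dtype=int))
    log = {
        "removed_missing": removed_missing,
        "removed_snps": snp_log,
        "removed_related": removed_related,
        "n_pruned_for_ibd": int(len(pruned_idx)),
    }
    return out, log
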