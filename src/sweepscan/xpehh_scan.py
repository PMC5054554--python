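"""Cross-population EHH (XP-EHH) per SNP.

For each core SNP, EHH is computed over all haplotypes of each
population (grouped initially by the core allele) and extended in both
directions until the combined two-population panel's EHH decays below a
truncation threshold (default 0.05) or the chromosome ends.  The
integrated area under each population's curve (trapezoidal rule over bp
distance, left + right) gives i_A and i_B; the raw statistic is
ln(i_A / i_B) and is standardized genome-wide (no frequency bins).  A
positive standardized score means longer haplotypes — candidate
selection — in population A.

Integration stops at the last marker before truncation, with no
extrapolation beyond the terminal marker; the same marker range is used
for both populations, which makes the statistic exactly antisymmetric
under a population-label swap.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .genotype_io import HaplotypeSet
from .ehh_scan import _homozygosity

__all__ = ["integrated_ehh", "xpehh"]


def _areas_one_direction(
    haps_a: np.ndarray,
    haps_b: np.ndarray,
    positions: np.ndarray,
    core: int,
    direction: str,
    truncation: float,
) -> tuple[float, float]:
    """Trapezoid areas (pop A, pop B) for one direction.

    Walks outward splitting identity groups in A, B and the pooled
    panel simultaneously; stops once pooled EHH < truncation (that
    marker is excluded — last-marker-before-truncation rule)."""
    step = -1 if direction == "left" else 1
    m = haps_a.shape[1]
    lab_a = haps_a[:, core].astype(np.int64)
    lab_b = haps_b[:, core].astype(np.int64)
    lab_c = np.concatenate([lab_a, lab_b])
    n_a = lab_a.size

    e_a = _homozygosity(lab_a)
    e_b = _homozygosity(lab_b)
    e_c = _homozygosity(lab_c)
    if e_c < truncation:
        return 0.0, 0.0
    xs = [0.0]
    ya = [e_a]
    yb = [e_b]
    j = core + step
    while 0 <= j < m:
        col = np.concatenate([haps_a[:, j], haps_b[:, j]])
        lab_c = lab_c * 2 + col
        _, lab_c = np.unique(lab_c, return_inverse=True)
        e_c = _homozygosity(lab_c)
        if e_c < truncation:
            break
        lab_a = lab_a * 2 + haps_a[:, j]
        _, lab_a = np.unique(lab_a, return_inverse=True)
        lab_b = lab_b * 2 + haps_b[:, j]
        _, lab_b = np.unique(lab_b, return_inverse=True)
        xs.append(abs(float(positions[j]) - float(positions[core])))
        ya.append(_homozygosity(lab_a))
        yb.append(_homozygosity(lab_b))
        j += step
    if len(xs) < 2:
        return 0.0, 0.0
    x = np.asarray(xs)
    return float(np.trapezoid(ya, x)), float(np.trapezoid(yb, x))


def integrated_ehh(
    hap_a: HaplotypeSet,
    hap_b: HaplotypeSet,
    core: int,
    truncation: float = 0.05,
) -> tuple[float, float]:
    """Integrated EHH areas (bp·EHH) for both populations at one core.

    Left and right areas are summed; the combined-panel truncation rule
    defines the integration range for both populations.
    """
    la, lb = _areas_one_direction(
        hap_a.haps, hap_b.haps, hap_a.positions, core, "left", truncation
    )
    ra, rb = _areas_one_direction(
        hap_a.haps, hap_b.haps, hap_a.positions, core, "right", truncation
    )
    return la + ra, lb + rb


def xpehh(
    hap_a: HaplotypeSet,
    hap_b: HaplotypeSet,
    truncation: float = 0.05,
) -> pd.DataFrame:
    """XP-EHH scan over a shared SNP map.

    Returns a table (snp, id, pos, i_a, i_b, raw, z) with
    raw = ln(i_A / i_B) and z standardized over the scan.  SNPs
    monomorphic in the combined panel, or with a zero area in either
    population, are skipped.
    """
    if hap_a.n_snps != hap_b.n_snps or not np.array_equal(hap_a.positions, hap_b.positions):
        raise ValueError("populations must share a SNP map")
    sm = hap_a.snp_map
    total = np.concatenate([hap_a.haps, hap_b.haps]).sum(axis=0)
    n_tot = hap_a.n_haplotypes + hap_b.n_haplotypes
    rows = []
    for core in range(hap_a.n_snps):
        if total[core] == 0 or total[core] == n_tot:
            continue
        i_a, i_b = integrated_ehh(hap_a, hap_b, core, truncation)
        if i_a <= 0.0 or i_b <= 0.0:
            continue
        rows.append(
            {
                "snp": core,
                "id": sm["id"].iloc[core],
                "chrom": sm["chrom"].iloc[core],
                "pos": int(sm["pos"].iloc[core]),
                "i_a": i_a,
                "i_b": i_b,
                # log difference (not log of the ratio) so the score
                # negates exactly under a population swap
                "raw": math.log(i_a) - math.log(i_b),
            }
        )
    df = pd.DataFrame(rows, columns=["snp", "id", "chrom", "pos", "i_a", "i_b", "raw"])
    if len(df) >= 2 and df["raw"].std(ddof=1) > 0:
        df["z"] = (df["raw"] - df["raw"].mean()) / df["raw"].std(ddof=1)
    else:
        df["z"] = np.nan
    return df
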