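"""Extended haplotype homozygosity and the long-range haplotype (LRH)
test within a population.

EHH at marker m for a core allele is the probability that two randomly
chosen haplotypes carrying that allele are identical over the interval
from the core SNP out to m:  EHH = sum_g C(k_g, 2) / C(c, 2) with c the
carrier count and k_g the sizes of the identical extended-haplotype
groups.  The relative EHH (REHH) divides the tested allele's EHH by the
EHH of all other core alleles combined, evaluated at the marker where
the combined-core EHH has decayed into a target band (0.03–0.05 around
0.04, within 1 Mb of the core).  ln(REHH) values are standardized to
zero mean / unit variance in 20 equal-width core-allele-frequency bins;
the standardized score is the LRH statistic.

Cores are single SNPs; both scan directions are kept as separate
score observations.  Distances are physical (bp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import HaplotypeSet

__all__ = [
    "EhhCurve",
    "ehh",
    "combined_ehh",
    "marker_h",
    "rehh",
    "lrh_scan",
    "standardize_lrh",
]


@dataclass
class EhhCurve:
    """EHH decay outward from a core SNP in one direction.

    ``marker_idx[0]`` is the core itself (distance 0); ``values[0]`` is
    1 for a per-allele curve and the core-SNP homozygosity for the
    combined curve.
    """

    core: int
    allele: int | None  # None for the combined (all-haplotype) curve
    direction: str  # "left" or "right"
    marker_idx: np.ndarray
    distance_bp: np.ndarray
    values: np.ndarray


def _homozygosity(labels: np.ndarray) -> float:
    """sum_g C(k_g, 2) / C(n, 2) over the label groups.

    ``labels`` must be non-negative compact group ids.
    """
    n = labels.size
    if n < 2:
        return float("nan")
    counts = np.bincount(labels)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _walk(
    haps: np.ndarray,
    positions: np.ndarray,
    rows: np.ndarray,
    core: int,
    direction: str,
    init_labels: np.ndarray,
    max_dist: int | None,
    stop_below: float | None,
) -> tuple[list[int], list[float]]:
    """Group-splitting outward walk; returns marker indices and EHH.

    The first entry is the core itself with the homozygosity of
    ``init_labels``.  Stops at ``max_dist`` bp, chromosome end, or once
    EHH drops below ``stop_below`` (that marker is still reported).
    """
    step = -1 if direction == "left" else 1
    m = haps.shape[1]
    labels = init_labels.astype(np.int64).copy()
    idxs = [core]
    vals = [_homozygosity(labels)]
    j = core + step
    while 0 <= j < m:
        if max_dist is not None and abs(int(positions[j]) - int(positions[core])) > max_dist:
            break
        labels = labels * 2 + haps[rows, j]
        # re-map to compact ids to keep values bounded
        _, labels = np.unique(labels, return_inverse=True)
        e = _homozygosity(labels)
        idxs.append(j)
        vals.append(e)
        if e == 0.0 or (stop_below is not None and e < stop_below):
            break
        j += step
    return idxs, vals


def ehh(
    hapset: HaplotypeSet,
    core: int,
    allele: int,
    direction: str,
    max_dist: int | None = 1_000_000,
) -> EhhCurve:
    """EHH decay curve for one core allele in one direction.

    Requires at least two carriers of the core allele.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    rows = np.nonzero(hapset.haps[:, core] == allele)[0]
    if rows.size < 2:
        raise ValueError(f"fewer than 2 carriers of allele {allele} at core {core}")
    init = np.zeros(rows.size, dtype=np.int64)
    idxs, vals = _walk(
        hapset.haps, hapset.positions, rows, core, direction, init, max_dist, stop_below=None
    )
    pos = hapset.positions
    return EhhCurve(
        core=core,
        allele=allele,
        direction=direction,
        marker_idx=np.asarray(idxs),
        distance_bp=np.abs(pos[np.asarray(idxs)] - pos[core]),
        values=np.asarray(vals),
    )


def combined_ehh(
    hapset: HaplotypeSet,
    core: int,
    direction: str,
    max_dist: int | None = 1_000_000,
    stop_below: float | None = None,
    rows: np.ndarray | None = None,
) -> EhhCurve:
    """EHH over all haplotypes, initially grouped by the core allele.

    At distance 0 this equals the core-SNP homozygosity; it is the curve
    on which the marker-H decay point is selected.
    """
    if rows is None:
        rows = np.arange(hapset.n_haplotypes)
    init = hapset.haps[rows, core].astype(np.int64)
    idxs, vals = _walk(
        hapset.haps, hapset.positions, rows, core, direction, init, max_dist, stop_below
    )
    pos = hapset.positions
    return EhhCurve(
        core=core,
        allele=None,
        direction=direction,
        marker_idx=np.asarray(idxs),
        distance_bp=np.abs(pos[np.asarray(idxs)] - pos[core]),
        values=np.asarray(vals),
    )


def marker_h(
    curve: EhhCurve,
    target: float = 0.04,
    band: tuple[float, float] = (0.03, 0.05),
    max_dist: int = 1_000_000,
) -> int | None:
    """First marker (moving outward) whose EHH lies within ``band``.

    Returns the SNP index, or None if the curve never enters the band
    within ``max_dist`` of the core (absence is a valid outcome — a
    region of extreme LD simply yields no test at this core).
    """
    lo, hi = band
    for k in range(1, len(curve.marker_idx)):
        if curve.distance_bp[k] > max_dist:
            break
        v = curve.values[k]
        if lo <= v <= hi:
            return int(curve.marker_idx[k])
    return None


def _ehh_at_marker(hapset: HaplotypeSet, core: int, allele: int, marker: int) -> float:
    """EHH of the carriers of ``allele`` over the interval [core..marker]."""
    rows = np.nonzero(hapset.haps[:, core] == allele)[0]
    if rows.size < 2:
        return float("nan")
    lo, hi = (marker, core) if marker < core else (core, marker)
    seg = hapset.haps[np.ix_(rows, np.arange(lo, hi + 1))]
    # group identical rows
    _, inv = np.unique(seg, axis=0, return_inverse=True)
    return _homozygosity(inv)


def rehh(
    hapset: HaplotypeSet,
    core: int,
    direction: str,
    target: float = 0.04,
    band: tuple[float, float] = (0.03, 0.05),
    max_dist: int = 1_000_000,
) -> dict[int, dict]:
    """REHH of each core allele at the marker-H decay point.

    Returns ``{allele: {"rehh", "ln_rehh", "freq", "marker"}}``;
    alleles with fewer than two carriers, an absent marker-H, or a zero
    denominator are omitted.
    """
    curve = combined_ehh(hapset, core, direction, max_dist=max_dist)
    mk = marker_h(curve, target=target, band=band, max_dist=max_dist)
    if mk is None:
        return {}
    out: dict[int, dict] = {}
    n = hapset.n_haplotypes
    n1 = int(hapset.haps[:, core].sum())
    counts = {0: n - n1, 1: n1}
    for allele in (0, 1):
        other = 1 - allele
        if counts[allele] < 2 or counts[other] < 2:
            continue
        e_a = _ehh_at_marker(hapset, core, allele, mk)
        e_o = _ehh_at_marker(hapset, core, other, mk)
        if not np.isfinite(e_a) or not np.isfinite(e_o) or e_o == 0.0 or e_a == 0.0:
            continue
        r = e_a / e_o
        out[allele] = {
            "rehh": float(r),
            "ln_rehh": float(math.log(r)),
            "freq": counts[allele] / n,
            "marker": mk,
        }
    return out


def lrh_scan(
    hapset: HaplotypeSet,
    target: float = 0.04,
    band: tuple[float, float] = (0.03, 0.05),
    max_dist: int = 1_000_000,
) -> pd.DataFrame:
    """REHH for every core SNP, allele and direction.

    Returns a long table (snp index, id, pos, allele, direction, freq,
    ln_rehh); pass it to :func:`standardize_lrh` to obtain LRH scores.
    """
    records = []
    sm = hapset.snp_map
    for core in range(hapset.n_snps):
        for direction in ("left", "right"):
            for allele, rec in rehh(
                hapset, core, direction, target=target, band=band, max_dist=max_dist
            ).items():
                records.append(
                    {
                        "snp": core,
                        "id": sm["id"].iloc[core],
                        "chrom": sm["chrom"].iloc[core],
                        "pos": int(sm["pos"].iloc[core]),
                        "allele": allele,
                        "direction": direction,
                        "freq": rec["freq"],
                        "rehh": rec["rehh"],
                        "ln_rehh": rec["ln_rehh"],
                    }
                )
    cols = ["snp", "id", "chrom", "pos", "allele", "direction", "freq", "rehh", "ln_rehh"]
    return pd.DataFrame(records, columns=cols)


def standardize_lrh(scan: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """Standardize ln(REHH) within equal-width core-allele-frequency bins.

    Bins cover [0, 1] in widths of ``1 / n_bins`` (the last bin is
    closed above).  Within each bin with at least two values and
    positive spread, z = (ln_rehh - bin mean) / bin SD (sample SD,
    ddof=1); otherwise z is NaN and the observation is excluded
    downstream.  Adds ``freq_bin`` and ``z`` columns.
    """
    out = scan.copy()
    if out.empty:
        out["freq_bin"] = pd.Series(dtype=int)
        out["z"] = pd.Series(dtype=float)
        return out
    freq = out["freq"].to_numpy()
    bins = np.minimum((freq * n_bins).astype(int), n_bins - 1)
    out["freq_bin"] = bins
    z = np.full(len(out), np.nan)
    vals = out["ln_rehh"].to_numpy()
    for b in np.unique(bins):
        sel = bins == b
        v = vals[sel]
        if v.size < 2:
            continue
        sd = v.std(ddof=1)
        if sd == 0:
            continue
        z[sel] = (v - v.mean()) / sd
    out["z"] = z
    return out
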