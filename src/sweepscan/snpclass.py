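"""Functional SNP classes, low-F_ST enrichment tests, and gene ranking
for candidate windows.

SNPs are classified into five classes — non-genic, intron, exon, 5'UTR,
3'UTR — from a feature annotation, with UTR > exon > intron precedence
when features overlap.  Because non-genic SNPs are taken as a neutral
demographic baseline, an excess of low-F_ST SNPs (membership in the
lowest-mean mixture component) in a class relative to non-genic SNPs
points to balancing or purifying selection on that class; the
comparison is a 2x2 chi-square test of independence (no continuity
correction), run overall and within 10 equal-width bins of the
unweighted two-population mean MAF over [0, 0.5].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = [
    "classify_snps",
    "maf_bins",
    "lowfst_enrichment",
    "rank_genes_lrh",
    "genes_near_peak",
]

CLASSES = ("non_genic", "intron", "exon", "utr5", "utr3")
_PRECEDENCE = {"utr5": 3, "utr3": 3, "exon": 2, "intron": 1}


def classify_snps(snp_map: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Assign each SNP exactly one functional class.

    ``annotation`` uses 1-based inclusive ``start``/``end`` with
    ``name`` in {utr5, utr3, exon, intron} (see genotype_io BED
    readers).  Overlapping features resolve by UTR > exon > intron;
    uncovered SNPs are non-genic.  Returns the SNP map plus a
    ``snp_class`` column.
    """
    bad = set(annotation["name"]) - set(_PRECEDENCE)
    if bad:
        raise ValueError(f"unknown feature types: {sorted(bad)}")
    out = snp_map.copy()
    cls = np.full(len(out), "non_genic", dtype=object)
    rank = np.zeros(len(out), dtype=int)
    for chrom, feats in annotation.groupby("chrom", sort=False):
        sel = np.nonzero((out["chrom"].astype(str) == str(chrom)).to_numpy())[0]
        if sel.size == 0:
            continue
        pos = out["pos"].to_numpy()[sel]
        for _, f in feats.iterrows():
            hit = (pos >= f["start"]) & (pos <= f["end"])
            r = _PRECEDENCE[f["name"]]
            for i in np.nonzero(hit)[0]:
                gi = sel[i]
                if r > rank[gi]:
                    rank[gi] = r
                    cls[gi] = f["name"]
    out["snp_class"] = cls
    return out


def maf_bins(maf_a: np.ndarray, maf_b: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Bin index (0..n_bins-1) of the unweighted mean MAF over [0, 0.5].

    Equal-width bins of 0.05; the top bin is closed above.
    """
    mean_maf = (np.asarray(maf_a, float) + np.asarray(maf_b, float)) / 2.0
    return np.minimum((mean_maf / 0.5 * n_bins).astype(int), n_bins - 1)


def _chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, bool]:
    """Chi-square of independence on [[a, b], [c, d]], no Yates
    correction; returns (stat, p, reliable) where reliable is False if
    any expected cell count is below 5."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0, False
    stat, p, _, expected = chi2_contingency(table, correction=False)
    return float(stat), float(p), bool((expected >= 5).all())


def lowfst_enrichment(
    records: pd.DataFrame,
    per_bin: bool = False,
) -> pd.DataFrame:
    """Excess/deficit of low-F_ST SNPs per class versus non-genic.

    ``records`` needs ``snp_class``, boolean ``low_fst``, and (when
    ``per_bin``) ``maf_bin``.  For each of the four genic classes the
    2x2 table (low_fst x {class, non_genic}) is tested; ``direction``
    reports whether the class has an excess or a deficit of low-F_ST
    SNPs relative to non-genic, and ``reliable`` is False when any
    expected cell is below 5 (the result is still reported).
    """
    def one_stratum(df: pd.DataFrame, bin_id) -> list[dict]:
        base = df[df["snp_class"] == "non_genic"]
        b_low = int(base["low_fst"].sum())
        b_not = int((~base["low_fst"]).sum())
        rows = []
        for c in ("intron", "exon", "utr5", "utr3"):
            sub = df[df["snp_class"] == c]
            c_low = int(sub["low_fst"].sum())
            c_not = int((~sub["low_fst"]).sum())
            stat, p, reliable = _chi2_2x2(c_low, c_not, b_low, b_not)
            frac_c = c_low / max(c_low + c_not, 1)
            frac_b = b_low / max(b_low + b_not, 1)
            rows.append(
                {
                    "maf_bin": bin_id,
                    "snp_class": c,
                    "n_class": c_low + c_not,
                    "low_fst_class": c_low,
                    "low_fst_non_genic": b_low,
                    "chi2": stat,
                    "p": p,
                    "direction": "excess" if frac_c > frac_b else "deficit",
                    "reliable": reliable,
                }
            )
        return rows

    rows: list[dict] = []
    if per_bin:
        for b, df in records.groupby("maf_bin", sort=True):
            rows.extend(one_stratum(df, int(b)))
    else:
        rows.extend(one_stratum(records, -1))
    return pd.DataFrame(rows)


def _gene_intervals(annotation: pd.DataFrame) -> pd.DataFrame:
    """Gene spans (min start, max end of its features) per gene_id."""
    g = annotation[annotation["gene_id"] != ""]
    if g.empty:
        return pd.DataFrame(columns=["gene_id", "chrom", "start", "end"])
    agg = g.groupby("gene_id").agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max")
    )
    return agg.reset_index()


def rank_genes_lrh(
    candidate_windows: pd.DataFrame,
    annotation: pd.DataFrame,
    theta: pd.DataFrame,
    flank_bp: int = 1000,
) -> pd.DataFrame:
    """Top gene per candidate window by mean F_ST over the gene ±1 kb.

    Each gene overlapping a window is scored by the mean theta_hat of
    SNPs inside [gene start - flank, gene end + flank]; the gene with
    the maximum score wins (ties: longer gene, then leftmost).  Windows
    with no overlapping gene are omitted.
    """
    genes = _gene_intervals(annotation)
    rows = []
    for _, w in candidate_windows.iterrows():
        over = genes[
            (genes["chrom"].astype(str) == str(w["chrom"]))
            & (genes["start"] < w["end"])
            & (genes["end"] >= w["start"])
        ]
        best = None
        for _, g in over.iterrows():
            sel = theta[
                (theta["chrom"].astype(str) == str(g["chrom"]))
                & (theta["pos"] >= g["start"] - flank_bp)
                & (theta["pos"] <= g["end"] + flank_bp)
            ]
            if sel.empty:
                continue
            score = float(sel["theta_hat"].mean())
            length = int(g["end"] - g["start"])
            key = (score, length, -int(g["start"]))
            if best is None or key > best[0]:
                best = (key, g["gene_id"], score)
        if best is not None:
            rows.append(
                {
                    "window": int(w["window"]),
                    "chrom": w["chrom"],
                    "start": int(w["start"]),
                    "end": int(w["end"]),
                    "gene_id": best[1],
                    "score": best[2],
                }
            )
    return pd.DataFrame(rows, columns=["window", "chrom", "start", "end", "gene_id", "score"])


def genes_near_peak(
    candidate_windows: pd.DataFrame,
    annotation: pd.DataFrame,
    radius_bp: int = 100_000,
) -> pd.DataFrame:
    """Genes whose span intersects ±radius around each window's peak SNP.

    ``candidate_windows`` needs a ``peak_pos`` column (the SNP with the
    maximum |XP-EHH| in the window).
    """
    genes = _gene_intervals(annotation)
    rows = []
    for _, w in candidate_windows.iterrows():
        lo = int(w["peak_pos"]) - radius_bp
        hi = int(w["peak_pos"]) + radius_bp
        over = genes[
            (genes["chrom"].astype(str) == str(w["chrom"]))
            & (genes["start"] <= hi)
            & (genes["end"] >= lo)
        ]
        for _, g in over.iterrows():
            rows.append(
                {
                    "window": int(w["window"]),
                    "peak_pos": int(w["peak_pos"]),
                    "gene_id": g["gene_id"],
                    "gene_start": int(g["start"]),
                    "gene_end": int(g["end"]),
                }
            )
    return pd.DataFrame(rows, columns=["window", "peak_pos", "gene_id", "gene_start", "gene_end"])
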