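"""Non-overlapping 500-kb windowing, SNP-count grouping and empirical-P
candidate calling.

Windows are anchored at bp 1 on each chromosome (half-open spans
[start, start + width)); terminal partial windows are retained but
flagged.  For the haplotype tests, windows are clustered into groups by
SNP count in increments of 20 (group_id = n_snps // 20), windows
outside per-test SNP-count bounds (40–200 for the LRH scan, 80–220 for
XP-EHH) are excluded, and within each group the empirical P of window i
is the fraction of windows whose statistic strictly exceeds window i's;
candidates are windows with empirical P below 1%.  Windowed mean F_ST
uses the extreme-quantile rule instead: candidates are windows at or
above the 97.5th percentile of the window means.

Strict ">" is used both in the f-value threshold (z > 2.6) and in
empirical-P counting, so ties favor candidacy.  No randomness anywhere
in this module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "make_windows",
    "assign_windows",
    "lrh_window_stat",
    "group_and_empirical_p",
    "fst_windows",
    "xpehh_windows",
]

WIDTH_DEFAULT = 500_000


def make_windows(snp_map: pd.DataFrame, width: int = WIDTH_DEFAULT) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping windows of ``width`` bp.

    Windows start at bp 1; ``end`` is exclusive.  The terminal window of
    a chromosome is retained and flagged ``partial`` when the last SNP
    falls short of a full width.  Returns (window, chrom, start, end,
    partial).
    """
    rows = []
    widx = 0
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        if grp.empty:
            continue
        last = int(grp["pos"].max())
        n_win = (last - 1) // width + 1
        for w in range(n_win):
            start = 1 + w * width
            end = start + width
            rows.append(
                {
                    "window": widx,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "partial": w == n_win - 1 and last < end - 1,
                }
            )
            widx += 1
    return pd.DataFrame(rows, columns=["window", "chrom", "start", "end", "partial"])


def assign_windows(
    windows: pd.DataFrame, chrom: pd.Series | np.ndarray, pos: pd.Series | np.ndarray
) -> np.ndarray:
    """Window id for each (chrom, pos); -1 when outside every window."""
    chrom = np.asarray(chrom).astype(str)
    pos = np.asarray(pos, dtype=np.int64)
    out = np.full(pos.size, -1, dtype=np.int64)
    for c, grp in windows.groupby("chrom", sort=False):
        sel = chrom == str(c)
        if not sel.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        ids = grp["window"].to_numpy()
        k = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = (k >= 0) & (pos[sel] < ends[np.clip(k, 0, len(ends) - 1)])
        res = np.where(ok, ids[np.clip(k, 0, len(ids) - 1)], -1)
        out[sel] = res
    return out


def lrh_window_stat(
    windows: pd.DataFrame, scores: pd.DataFrame, threshold: float = 2.6
) -> pd.DataFrame:
    """Per-window f value: the share of score observations with z above
    the threshold.

    ``scores`` is the standardized LRH table (needs chrom, pos, snp, z);
    observations with NaN z are dropped.  Both directions and both
    alleles count as separate observations; ``n_snps`` counts distinct
    SNPs with at least one valid score (the windows' grouping variable).
    Windows without observations get NaN f.
    """
    sc = scores.dropna(subset=["z"]).copy()
    sc["window"] = assign_windows(windows, sc["chrom"], sc["pos"])
    sc = sc[sc["window"] >= 0]
    grp = sc.groupby("window")
    f = grp["z"].apply(lambda v: float((v > threshold).mean()))
    n_obs = grp["z"].size()
    n_snps = grp["snp"].nunique()
    out = windows.copy()
    out["n_snps"] = out["window"].map(n_snps).fillna(0).astype(int)
    out["n_obs"] = out["window"].map(n_obs).fillna(0).astype(int)
    out["stat"] = out["window"].map(f)
    return out


def group_and_empirical_p(
    windows: pd.DataFrame,
    stat_col: str = "stat",
    group_increment: int = 20,
    min_snps: int = 40,
    max_snps: int = 200,
    alpha: float = 0.01,
    min_group_size: int = 100,
) -> pd.DataFrame:
    """Group windows by SNP count and attach empirical P values.

    Windows with fewer than ``min_snps`` or more than ``max_snps`` SNPs
    are excluded from the returned table.  Within each group
    (group_id = n_snps // increment), empirical_p(i) is the fraction of
    the group's windows whose statistic strictly exceeds window i's;
    ``candidate`` flags empirical_p < alpha.  Groups smaller than
    ``min_group_size`` cannot resolve P < 1% and are flagged
    ``small_group``.
    """
    w = windows.dropna(subset=[stat_col]).copy()
    w = w[(w["n_snps"] >= min_snps) & (w["n_snps"] <= max_snps)].copy()
    w["group_id"] = w["n_snps"] // group_increment
    emp = np.full(len(w), np.nan)
    small = np.zeros(len(w), dtype=bool)
    stats = w[stat_col].to_numpy()
    gids = w["group_id"].to_numpy()
    for g in np.unique(gids):
        sel = gids == g
        vals = stats[sel]
        # fraction of the group strictly above each value
        order = np.sort(vals)
        n = vals.size
        above = n - np.searchsorted(order, vals, side="right")
        emp[sel] = above / n
        small[sel] = n < min_group_size
    w["empirical_p"] = emp
    w["small_group"] = small
    w["candidate"] = w["empirical_p"] < alpha
    return w


def fst_windows(
    windows: pd.DataFrame,
    theta: pd.DataFrame,
    quantile: float = 0.975,
) -> pd.DataFrame:
    """Windowed mean theta_hat with the extreme-quantile candidate rule.

    ``theta`` needs chrom, pos, theta_hat.  Windows with no SNPs are
    excluded; candidates are windows whose mean is at or above the
    ``quantile`` point of the window-mean distribution.  When every
    window mean is identical the quantile degenerates and all windows
    are flagged (with ``degenerate`` set).
    """
    th = theta.dropna(subset=["theta_hat"]).copy()
    th["window"] = assign_windows(windows, th["chrom"], th["pos"])
    th = th[th["window"] >= 0]
    grp = th.groupby("window")["theta_hat"]
    out = windows.copy()
    out["n_snps"] = out["window"].map(grp.size()).fillna(0).astype(int)
    out["stat"] = out["window"].map(grp.mean())
    out = out[out["n_snps"] > 0].copy()
    cut = float(np.quantile(out["stat"].to_numpy(), quantile))
    out["candidate"] = out["stat"] >= cut
    out["degenerate"] = bool(out["stat"].nunique() == 1)
    return out


def xpehh_windows(
    windows: pd.DataFrame,
    scores: pd.DataFrame,
    group_increment: int = 20,
    min_snps: int = 80,
    max_snps: int = 220,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Max-|z| window statistic with sign-based population attribution.

    The window statistic is the largest |z|; the sign of the signed z
    attaining it attributes a candidate window to population A
    (positive) or B (negative).  Empirical-P machinery as in
    :func:`group_and_empirical_p` with the XP-EHH SNP-count bounds.
    """
    sc = scores.dropna(subset=["z"]).copy()
    sc["window"] = assign_windows(windows, sc["chrom"], sc["pos"])
    sc = sc[sc["window"] >= 0]

    def peak(v: pd.Series) -> pd.Series:
        i = v.abs().idxmax()
        return pd.Series({"stat": abs(v.loc[i]), "signed_max": v.loc[i]})

    grp = sc.groupby("window")
    agg = grp["z"].apply(peak).unstack()
    out = windows.copy()
    out["n_snps"] = out["window"].map(grp["z"].size()).fillna(0).astype(int)
    out["stat"] = out["window"].map(agg["stat"])
    out["signed_max"] = out["window"].map(agg["signed_max"])
    peak_pos = sc.groupby("window")[["z", "pos"]].apply(
        lambda d: int(d.loc[d["z"].abs().idxmax(), "pos"])
    )
    out["peak_pos"] = out["window"].map(peak_pos)
    out = group_and_empirical_p(
        out,
        stat_col="stat",
        group_increment=group_increment,
        min_snps=min_snps,
        max_snps=max_snps,
        alpha=alpha,
    )
    out["attributed_pop"] = np.where(out["signed_max"] > 0, "A", "B")
    return out
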