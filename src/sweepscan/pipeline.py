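"""End-to-end orchestration: simulate → qc → blocks / lrh / xpehh / fst
→ windows → snpclass, with a run manifest and candidate-overlap summary.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype_io import write_phased_vcf, write_bed_annotation, allele_counts
from .simdata import SimConfig, simulate_two_pop, emit_annotation, write_truth
from .qc import GenotypeTable, QcThresholds, run_qc
from .ldblocks import gabriel_blocks, block_summary, blocks_table
from .ehh_scan import lrh_scan, standardize_lrh
from .xpehh_scan import xpehh
from .fst_bayes import bayes_fst_scan, fit_theta_mixture, assign_components, BALANCING
from .window_scan import (
    make_windows,
    lrh_window_stat,
    group_and_empirical_p,
    fst_windows,
    xpehh_windows,
)
from .snpclass import classify_snps, maf_bins, lowfst_enrichment

__all__ = ["RunConfig", "run_all", "read_config", "overlap_matrix"]


@dataclass
class RunConfig:
    """Resolved parameters of a full run (defaults follow the scan's
    published thresholds; simulation sizes are desk-scale)."""

    out_dir: str = "sweepscan_out"
    seed: int = 1
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    gene_density: float = 0.3
    block_max_span: int = 500_000
    marker_h_target: float = 0.04
    marker_h_band: tuple[float, float] = (0.03, 0.05)
    max_dist: int = 1_000_000
    lrh_threshold: float = 2.6
    xpehh_truncation: float = 0.05
    window_width: int = 500_000
    group_increment: int = 20
    lrh_bounds: tuple[int, int] = (40, 200)
    xpehh_bounds: tuple[int, int] = (80, 220)
    alpha: float = 0.01
    fst_quantile: float = 0.975
    fst_draws: int = 1000
    mixture_kmax: int = 8
    run_blocks: bool = True

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


def read_config(path: str | os.PathLike) -> RunConfig:
    """Plain key=value config file → RunConfig.

    Keys matching RunConfig fields are set directly; ``sim.*`` and
    ``qc.*`` prefixes reach into the nested configs.  Values are parsed
    as int, then float, then left as strings.
    """
    cfg = RunConfig()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            target, attr = cfg, key
            if key.startswith("sim."):
                target, attr = cfg.sim, key[4:]
            elif key.startswith("qc."):
                target, attr = cfg.qc, key[3:]
            if not hasattr(target, attr):
                raise ValueError(f"unknown config key: {key}")
            cur = getattr(target, attr)
            if isinstance(cur, bool):
                parsed = val.lower() in ("1", "true", "yes")
            elif isinstance(cur, tuple):
                parts = [p.strip() for p in val.split(",")]
                parsed = tuple(float(p) if "." in p else int(p) for p in parts)
            else:
                try:
                    parsed = int(val)
                except ValueError:
                    try:
                        parsed = float(val)
                    except ValueError:
                        parsed = val
            setattr(target, attr, parsed)
    return cfg


def overlap_matrix(candidate_sets: dict[str, set[int]]) -> pd.DataFrame:
    """Pairwise counts of shared candidate windows between tests."""
    names = list(candidate_sets)
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            mat.loc[a, b] = len(candidate_sets[a] & candidate_sets[b])
    return mat


def run_all(config: RunConfig) -> Path:
    """Run the whole pipeline into ``config.out_dir``; deterministic
    under a fixed seed.  Returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.sim.seed = config.seed

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    hap_a, hap_b, truth = stage("simulate", simulate_two_pop, config.sim)
    write_phased_vcf(hap_a, out / "popA.vcf")
    write_phased_vcf(hap_b, out / "popB.vcf")
    write_truth(truth, out / "truth.tsv")
    ann = stage("annotation", emit_annotation, hap_a.snp_map, config.gene_density, config.seed)
    write_bed_annotation(ann, out / "genes.bed")

    # QC: simulated data is phased/complete, so this checks SNP filters
    # (MAF kept off for the between-population tests) and relatedness.
    logs = {}
    for name, hs in (("popA", hap_a), ("popB", hap_b)):
        _, qlog = stage("qc", run_qc, GenotypeTable.from_haplotypes(hs), config.qc, False)
        logs[name] = {
            "removed_missing": qlog["removed_missing"],
            "removed_related": qlog["removed_related"],
            "n_removed_snps": int(len(qlog["removed_snps"])),
        }
    (out / "qc_log.json").write_text(json.dumps(logs, indent=2))

    if config.run_blocks:
        summaries = {}
        for name, hs in (("popA", hap_a), ("popB", hap_b)):
            blocks = stage("blocks", gabriel_blocks, hs, config.block_max_span)
            blocks_table(blocks).to_csv(out / f"blocks_{name}.tsv", sep="\t", index=False)
            summaries[name] = block_summary(blocks)
        (out / "blocks_summary.json").write_text(json.dumps(summaries, indent=2))

    windows = make_windows(hap_a.snp_map, config.window_width)
    candidates: dict[str, set[int]] = {}

    for name, hs in (("lrh_popA", hap_a), ("lrh_popB", hap_b)):
        scan = stage(
            "lrh",
            lrh_scan,
            hs,
            config.marker_h_target,
            config.marker_h_band,
            config.max_dist,
        )
        scan = standardize_lrh(scan)
        scan.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        wstat = lrh_window_stat(windows, scan, config.lrh_threshold)
        wtab = group_and_empirical_p(
            wstat,
            group_increment=config.group_increment,
            min_snps=config.lrh_bounds[0],
            max_snps=config.lrh_bounds[1],
            alpha=config.alpha,
        )
        wtab.to_csv(out / f"{name}_windows.tsv", sep="\t", index=False)
        candidates[name] = set(wtab.loc[wtab["candidate"], "window"])

    xp = stage("xpehh", xpehh, hap_a, hap_b, config.xpehh_truncation)
    xp.to_csv(out / "xpehh.tsv", sep="\t", index=False)
    xpw = xpehh_windows(
        windows,
        xp,
        group_increment=config.group_increment,
        min_snps=config.xpehh_bounds[0],
        max_snps=config.xpehh_bounds[1],
        alpha=config.alpha,
    )
    xpw.to_csv(out / "xpehh_windows.tsv", sep="\t", index=False)
    candidates["xpehh_popA"] = set(xpw.loc[xpw["candidate"] & (xpw["attributed_pop"] == "A"), "window"])
    candidates["xpehh_popB"] = set(xpw.loc[xpw["candidate"] & (xpw["attributed_pop"] == "B"), "window"])

    theta = stage("fst", bayes_fst_scan, hap_a, hap_b, config.fst_draws, config.seed)
    fit = stage(
        "mixture", fit_theta_mixture, theta["theta_hat"].to_numpy(), (1, config.mixture_kmax), config.seed
    )
    assign, labels = assign_components(fit)
    valid = theta["theta_hat"].notna().to_numpy()
    comp = np.full(len(theta), -1)
    comp[valid] = assign
    theta["component"] = comp
    theta.to_csv(out / "fst.tsv", sep="\t", index=False)
    fit.model_table.to_csv(out / "fst_model_selection.tsv", sep="\t", index=False)
    fstw = fst_windows(windows, theta, config.fst_quantile)
    fstw.to_csv(out / "fst_windows.tsv", sep="\t", index=False)
    candidates["fst"] = set(fstw.loc[fstw["candidate"], "window"])

    overlap = overlap_matrix(candidates)
    overlap.to_csv(out / "overlap_matrix.tsv", sep="\t")

    # SNP classes and low-F_ST enrichment
    low_comp = [c for c, lab in labels.items() if lab == BALANCING]
    records = classify_snps(hap_a.snp_map, ann)
    records["low_fst"] = np.isin(comp, low_comp)
    maf_a = allele_counts(hap_a)["maf"].to_numpy()
    maf_b = allele_counts(hap_b)["maf"].to_numpy()
    records["maf_bin"] = maf_bins(maf_a, maf_b)
    records.to_csv(out / "snp_classes.tsv", sep="\t", index=False)
    lowfst_enrichment(records).to_csv(out / "enrichment_overall.tsv", sep="\t", index=False)
    lowfst_enrichment(records, per_bin=True).to_csv(
        out / "enrichment_by_maf_bin.tsv", sep="\t", index=False
    )

    (out / "manifest.json").write_text(json.dumps(config.manifest(), indent=2, default=str))
    return out
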