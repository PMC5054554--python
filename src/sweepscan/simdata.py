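"""Forward Wright–Fisher simulation of two diverged populations.

The generator emulates the data regime the scan statistics are designed
for: two populations split from a common ancestor, linkage
disequilibrium produced by finite recombination in a finite population,
a chip-like site-frequency spectrum with many low-MAF variants, and an
optional locus under divergent directional selection in population A
(high differentiation, long swept haplotypes, elevated cross-population
haplotype scores toward A).

Design: a forward (not coalescent) simulation, initialised from an
ancestral pool whose per-site allele frequencies follow a Beta(0.2, 0.2)
spectrum, with a neutral burn-in phase in the ancestral population to
build up LD before the split.  Recombination is a Poisson number of
crossovers per meiosis with uniform breakpoints.  Selection acts only in
population A (symmetric selection available, off by default): the
favored-allele count trajectory is drawn first from a dedicated RNG
stream as a deterministic additive-selection update (relative fitnesses
1, 1+s, 1+2s) followed by binomial drift, and haplotype transmission is
then conditioned on that trajectory generation by generation.  This
makes the trajectory exactly reproducible by a scalar simulator sharing
the seed stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import HaplotypeSet

__all__ = [
    "SimConfig",
    "SweepTruth",
    "simulate_two_pop",
    "selection_trajectory",
    "emit_annotation",
    "write_truth",
]

# RNG sub-stream tags (seed sequence spawn keys)
_TRAJ_TAG = 11
_MAIN_TAG = 13

# founder sites simulated per requested output site (drift losses)
_OVERSAMPLE = 4


@dataclass
class SimConfig:
    """Parameters of the two-population simulation.

    All sizes are diploid individuals; ``rec_rate`` is the per-bp
    per-generation crossover probability; ``sel_coef`` is the additive
    selection coefficient ``s`` applied in population A only (genotype
    fitnesses 1, 1+s, 1+2s).  ``sel_pos_bp is None`` disables selection.
    """

    n_anc: int = 100
    n_pop: int = 100
    g_split: int = 16
    g_burnin: int = 100
    seq_len_bp: int = 10_000_000
    n_snps: int = 1_000
    rec_rate: float = 1e-7
    sel_pos_bp: int | None = None
    sel_coef: float = 0.0
    sel_init_freq: float = 0.1
    sel_stop_freq: float | None = None
    sel_symmetric: bool = False
    max_retries: int = 20
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_anc", "n_pop", "seq_len_bp", "n_snps"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("g_split", "g_burnin", "max_retries"):
            if int(getattr(self, name)) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.rec_rate < 0:
            raise ValueError("rec_rate must be >= 0")
        if self.sel_pos_bp is not None:
            if not (0 <= self.sel_pos_bp < self.seq_len_bp):
                raise ValueError("sel_pos_bp must lie in [0, seq_len_bp)")
            if not (0.0 < self.sel_init_freq < 1.0):
                raise ValueError("sel_init_freq must lie in (0, 1)")

    @property
    def selection_enabled(self) -> bool:
        return self.sel_pos_bp is not None and self.sel_coef != 0.0


@dataclass
class SweepTruth:
    """Ground truth of the simulated selected locus (for recovery tests)."""

    sel_pos_bp: int | None
    sel_coef: float
    final_freq_popA: float | None
    final_freq_popB: float | None


class SweepLostError(RuntimeError):
    """Favored allele lost in every trajectory attempt."""


def selection_trajectory(
    n_dip: int,
    s: float,
    k0: int,
    generations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Favored-allele count trajectory under additive selection + drift.

    Starting from ``k0`` copies among ``2 * n_dip`` gametes, each
    generation applies the deterministic additive update
    ``p* = p (1 + s (1 + p)) / (1 + 2 s p)`` and then binomial sampling
    of ``2 * n_dip`` gametes.  Returns counts of length
    ``generations + 1`` including the start.
    """
    two_n = 2 * n_dip
    counts = np.empty(generations + 1, dtype=np.int64)
    counts[0] = k0
    k = k0
    for t in range(1, generations + 1):
        p = k / two_n
        p_star = p * (1.0 + s * (1.0 + p)) / (1.0 + 2.0 * s * p)
        k = int(rng.binomial(two_n, min(max(p_star, 0.0), 1.0)))
        counts[t] = k
    return counts


def _make_gametes(
    pop: np.ndarray,
    n_gametes: int,
    xover_mean: float,
    positions: np.ndarray,
    seq_len: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n_gametes`` recombinant gametes from diploid parents.

    ``pop`` holds 2 rows per parent.  Crossover count per meiosis is
    Poisson(``xover_mean``) with uniform bp breakpoints; gametes without
    crossovers are bulk-copied.
    """
    n_par = pop.shape[0] // 2
    m = pop.shape[1]
    parents = rng.integers(0, n_par, size=n_gametes)
    start_hap = rng.integers(0, 2, size=n_gametes)
    n_x = rng.poisson(xover_mean, size=n_gametes)
    out = np.empty((n_gametes, m), dtype=pop.dtype)
    plain = n_x == 0
    out[plain] = pop[2 * parents[plain] + start_hap[plain]]
    for g in np.nonzero(~plain)[0]:
        bp = np.sort(rng.uniform(0, seq_len, size=n_x[g]))
        # segment index at each SNP: number of breakpoints to its left
        seg = np.searchsorted(bp, positions)
        which = (start_hap[g] + seg) % 2
        h0 = pop[2 * parents[g]]
        h1 = pop[2 * parents[g] + 1]
        out[g] = np.where(which == 0, h0, h1)
    return out


def _single_gamete(
    pop: np.ndarray,
    xover_mean: float,
    positions: np.ndarray,
    seq_len: int,
    rng: np.random.Generator,
) -> np.ndarray:
    return _make_gametes(pop, 1, xover_mean, positions, seq_len, rng)[0]


def _condition_on_count(
    gametes: np.ndarray,
    parent_pop: np.ndarray,
    sel_idx: int,
    target: int,
    xover_mean: float,
    positions: np.ndarray,
    seq_len: int,
    rng: np.random.Generator,
) -> None:
    """Redraw individual gametes until exactly ``target`` carry allele 1
    at ``sel_idx`` (rejection sampling of (parent, meiosis) pairs)."""
    carriers = gametes[:, sel_idx] == 1
    excess = int(carriers.sum()) - target
    if excess == 0:
        return
    want_allele = 0 if excess > 0 else 1
    pool = np.nonzero(carriers if excess > 0 else ~carriers)[0]
    fix = rng.choice(pool, size=abs(excess), replace=False)
    parent_has = parent_pop[:, sel_idx] == want_allele
    if not parent_has.any():
        raise SweepLostError("required allele absent from parent population")
    for g in fix:
        for _ in range(10_000):
            cand = _single_gamete(parent_pop, xover_mean, positions, seq_len, rng)
            if cand[sel_idx] == want_allele:
                gametes[g] = cand
                break
        else:  # pragma: no cover - astronomically unlikely given parent_has
            raise SweepLostError("rejection sampling failed to produce required allele")


def simulate_two_pop(config: SimConfig) -> tuple[HaplotypeSet, HaplotypeSet, SweepTruth]:
    """Simulate two populations split from a common ancestor.

    Returns phased haplotype sets for populations A and B over an
    identical SNP map (sites monomorphic in both populations dropped)
    plus the :class:`SweepTruth` record.  Identical configs (including
    seed) give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _MAIN_TAG])
    seq_len = int(config.seq_len_bp)
    xover = config.rec_rate * seq_len

    # SNP positions and ancestral founder pool: Beta(0.2, 0.2) frequency
    # spectrum mimics a chip-like U-shaped MAF distribution.  Sites are
    # oversampled because drift fixes a share of them before sampling;
    # the output is thinned back to n_snps segregating sites.
    n_raw = min(_OVERSAMPLE * config.n_snps, max(config.seq_len_bp // 2, config.n_snps))
    positions = np.sort(rng.choice(seq_len, size=n_raw, replace=False)) + 1
    p_anc = rng.beta(0.2, 0.2, size=n_raw)
    anc = (rng.random((2 * config.n_anc, n_raw)) < p_anc).astype(np.int8)
    for _ in range(5):  # founder columns must segregate
        f = anc.mean(axis=0)
        mono = np.nonzero((f == 0) | (f == 1))[0]
        if mono.size == 0:
            break
        p_new = rng.beta(0.2, 0.2, size=mono.size)
        anc[:, mono] = (rng.random((2 * config.n_anc, mono.size)) < p_new).astype(np.int8)

    for _ in range(config.g_burnin):
        anc = _make_gametes(anc, 2 * config.n_anc, xover, positions, seq_len, rng)

    sel_idx: int | None = None
    traj: np.ndarray | None = None
    if config.selection_enabled:
        freq = anc.mean(axis=0)
        seg = np.nonzero((freq > 0) & (freq < 1))[0]
        if seg.size == 0:
            raise SweepLostError("no segregating site available for selection")
        cand = seg
        for tol in (0.01, 0.02, 0.05, 0.1):  # stay close to the requested position
            near = seg[np.abs(positions[seg] - config.sel_pos_bp) <= tol * seq_len]
            if near.size:
                cand = near
                break
        sel_idx = int(cand[np.argmin(np.abs(freq[cand] - config.sel_init_freq))])
        # trajectory drawn from its own stream so that a scalar
        # simulator with the same seed reproduces it exactly
        k0 = int(round(2 * config.n_pop * config.sel_init_freq))
        k0 = min(max(k0, 1), 2 * config.n_pop - 1)
        traj = None
        for attempt in range(config.max_retries + 1):
            t_rng = np.random.default_rng([config.seed, _TRAJ_TAG, attempt])
            cand_traj = selection_trajectory(
                config.n_pop, config.sel_coef, k0, config.g_split, t_rng
            )
            if config.sel_stop_freq is not None:
                # selection sustained until the favored allele reaches the
                # stop frequency; sampling happens at that generation
                target = config.sel_stop_freq * 2 * config.n_pop
                hit = np.nonzero(cand_traj >= target)[0]
                if hit.size:
                    traj = cand_traj[: int(hit[0]) + 1]
                    break
            elif cand_traj[-1] > 0:
                traj = cand_traj
                break
        if traj is None:
            raise SweepLostError(
                f"favored allele lost in all {config.max_retries + 1} trajectory attempts"
            )

    two_n = 2 * config.n_pop
    n_gens = (len(traj) - 1) if traj is not None else config.g_split

    def found_and_evolve(selected: bool) -> np.ndarray:
        pop = _make_gametes(anc, two_n, xover, positions, seq_len, rng)
        if selected:
            _condition_on_count(pop, anc, sel_idx, int(traj[0]), xover, positions, seq_len, rng)
        for t in range(1, n_gens + 1):
            nxt = _make_gametes(pop, two_n, xover, positions, seq_len, rng)
            if selected:
                _condition_on_count(
                    nxt, pop, sel_idx, int(traj[t]), xover, positions, seq_len, rng
                )
            pop = nxt
        return pop

    pop_a = found_and_evolve(config.selection_enabled)
    pop_b = found_and_evolve(config.selection_enabled and config.sel_symmetric)

    freq_a = pop_a.mean(axis=0)
    freq_b = pop_b.mean(axis=0)
    keep = np.nonzero(((freq_a > 0) | (freq_b > 0)) & ((freq_a < 1) | (freq_b < 1)))[0]
    if keep.size > config.n_snps:
        pick = np.unique(np.linspace(0, keep.size - 1, config.n_snps).round().astype(int))
        sub = keep[pick]
        if sel_idx is not None and sel_idx in keep and sel_idx not in sub:
            # keep the selected site; drop its nearest picked neighbor
            j = int(np.argmin(np.abs(sub - sel_idx)))
            sub[j] = sel_idx
            sub = np.sort(sub)
        keep = sub

    truth = SweepTruth(
        sel_pos_bp=int(positions[sel_idx]) if sel_idx is not None else None,
        sel_coef=config.sel_coef if config.selection_enabled else 0.0,
        final_freq_popA=float(freq_a[sel_idx]) if sel_idx is not None else None,
        final_freq_popB=float(freq_b[sel_idx]) if sel_idx is not None else None,
    )

    snp_map = pd.DataFrame(
        {
            "id": [f"snp{j:06d}" for j in keep],
            "chrom": "1",
            "pos": positions[keep],
            "allele0": "A",
            "allele1": "G",
        }
    )
    sample_ids_a = [f"A{i:04d}" for i in range(config.n_pop)]
    sample_ids_b = [f"B{i:04d}" for i in range(config.n_pop)]
    hs_a = HaplotypeSet(pop_a[:, keep], snp_map, sample_ids_a, pop_label="popA")
    hs_b = HaplotypeSet(pop_b[:, keep], snp_map.copy(), sample_ids_b, pop_label="popB")
    return hs_a, hs_b, truth


def write_truth(truth: SweepTruth, path) -> None:
    """Tab-separated ground-truth sidecar."""
    with open(path, "w") as fh:
        fh.write("sel_pos_bp\tsel_coef\tfinal_freq_popA\tfinal_freq_popB\n")
        fa = "NA" if truth.final_freq_popA is None else f"{truth.final_freq_popA:.6g}"
        fb = "NA" if truth.final_freq_popB is None else f"{truth.final_freq_popB:.6g}"
        fh.write(f"{truth.sel_pos_bp}\t{truth.sel_coef}\t{fa}\t{fb}\n")


# ---------------------------------------------------------------------------
# Random gene annotation


def emit_annotation(
    snp_map: pd.DataFrame,
    gene_density: float,
    seed: int,
    mean_gene_len: int = 20_000,
) -> pd.DataFrame:
    """Random non-overlapping gene models covering ~``gene_density`` of
    the region.

    Genes are laid down left to right with exponential intergenic gaps
    tuned so genic coverage approximates the requested fraction; each
    gene is utr5 | exon (intron exon)* | utr3.  Every SNP falls in
    exactly one of the five classes (anything uncovered is non-genic).
    Returns a feature table with 1-based inclusive ``start``/``end``,
    ``name`` in {utr5, exon, intron, utr3} and ``gene_id``.
    """
    if not (0.0 < gene_density < 1.0):
        raise ValueError("gene_density must lie in (0, 1)")
    if snp_map.empty:
        raise ValueError("SNP map is empty")
    rng = np.random.default_rng([int(seed), 29])
    chrom = snp_map["chrom"].iloc[0]
    region_end = int(snp_map["pos"].max()) + 1000
    mean_gap = mean_gene_len * (1.0 - gene_density) / gene_density

    rows = []
    cursor = 1
    gene_no = 0
    while True:
        cursor += int(rng.exponential(mean_gap)) + 1
        glen = max(int(rng.exponential(mean_gene_len)), 600)
        if cursor + glen > region_end:
            break
        gene_no += 1
        gid = f"gene{gene_no:04d}"
        utr5 = max(int(0.05 * glen), 50)
        utr3 = max(int(0.08 * glen), 50)
        body = glen - utr5 - utr3
        n_exons = 1 + int(rng.integers(0, 6))
        # split body into alternating exons/introns (exons ~1/4 of body)
        exon_total = max(int(0.25 * body), n_exons)
        exon_lens = np.maximum((rng.dirichlet(np.ones(n_exons)) * exon_total).astype(int), 1)
        intron_total = body - int(exon_lens.sum())
        if n_exons > 1 and intron_total >= n_exons - 1:
            intron_lens = np.maximum(
                (rng.dirichlet(np.ones(n_exons - 1)) * intron_total).astype(int), 1
            )
        else:
            intron_lens = np.zeros(max(n_exons - 1, 0), dtype=int)
        pos = cursor
        rows.append((chrom, pos, pos + utr5 - 1, "utr5", gid))
        pos += utr5
        for e in range(n_exons):
            rows.append((chrom, pos, pos + int(exon_lens[e]) - 1, "exon", gid))
            pos += int(exon_lens[e])
            if e < n_exons - 1 and intron_lens[e] > 0:
                rows.append((chrom, pos, pos + int(intron_lens[e]) - 1, "intron", gid))
                pos += int(intron_lens[e])
        rows.append((chrom, pos, pos + utr3 - 1, "utr3", gid))
        cursor = pos + utr3
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "gene_id"])
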