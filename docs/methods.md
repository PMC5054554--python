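# Methods

`sweepscan` implements a composite genome scan for recent positive
selection in livestock-style SNP-chip data: a within-population
long-range haplotype (LRH) test built on extended haplotype
homozygosity (EHH), the cross-population XP-EHH statistic, a Bayesian
per-locus F_ST estimator with a finite-mixture decomposition, Gabriel
haplotype-block partitioning, and window-based empirical-P candidate
calling. A forward Wright–Fisher simulator provides controlled inputs
with known ground truth. This note records the models, the parameters
that matter, and the design choices made where the design was genuinely
open.

## Haplotype statistics

**EHH.** For a core SNP and core allele, EHH at marker m is the
probability that two randomly drawn carrier chromosomes are identical
over the interval [core..m]:

    EHH = sum_g C(k_g, 2) / C(c, 2)

with c carriers partitioned into identity groups of sizes k_g. The
implementation walks outward from the core, splitting groups marker by
marker (labels doubled plus the next allele, recompacted); a dedicated
all-pairs oracle in the test suite checks exact agreement. EHH is 1 at
the core, non-increasing outward, and in [0, 1].

**REHH / LRH.** The decay point ("marker H") is chosen on the
combined-core curve — EHH over *all* haplotypes with the initial
partition by core allele — as the first marker outward whose EHH lies
in the band [0.03, 0.05] around the 0.04 target, within 1 Mb of the
core. Where extreme LD keeps the combined curve above the band for a
full megabase (the known failure mode of single-SNP LRH scans in
strong-LD genomes) the core yields no test; absence is a recorded,
valid outcome. REHH is the ratio of the tested allele's EHH to the
opposite allele's EHH at marker H; ln(REHH) values are standardized to
zero mean and unit sample variance (ddof = 1) within 20 equal-width
core-allele-frequency bins. Both scan directions are kept as separate
observations; single-SNP cores only. Physical distance is used
throughout, with 1 cM/Mb assumed wherever map distance is quoted.

**XP-EHH.** Per core SNP, each population's EHH (all haplotypes,
initial split by core allele) is integrated by the trapezoidal rule
over bp distance, left plus right, until the *combined* two-population
panel's EHH drops below 0.05 or the chromosome ends; integration stops
at the last marker before truncation with no extrapolation. The raw
statistic ln(i_A / i_B) is standardized genome-wide (no frequency
bins). Because the truncation range is shared, the raw score negates
exactly under a population-label swap. Positive standardized scores
mean longer haplotypes — candidate selection — in population A.

## Bayesian F_ST

With a Beta(1/2, 1/2) prior, allele counts (n_A, n_a) give a
Beta(n_A + 1/2, n_a + 1/2) posterior per population. S = 1,000 joint
draws per locus (a package default; seedable) are mapped draw-by-draw
through

    theta = [ sum_r p_r^2 - (sum_r p_r)^2 / R ] /
            [ ( R sum_r p_r - (sum_r p_r)^2 ) / R ]

and averaged into the point estimate theta_hat. Draws with a
degenerate denominator (all frequencies 0 or all 1) are skipped rather
than clamped — the mean over valid draws stays unbiased; a locus with
no valid draw is excluded. The estimator is not range-constrained and
can go slightly negative at undifferentiated loci.

The genome-wide theta_hat distribution is decomposed with univariate
Gaussian mixtures fitted by EM for k = 1..8, model choice by
AIC = -2 loglik + 2(3k - 1), loci assigned to the arg-max
responsibility component (ties to the lower index). The components
with the highest and lowest means are the directional- and
balancing/purifying-selection candidates. Numerical choices: means are
initialized from 1-D k-means (quantile seeds plus random-data-point
seeds, 3 starts by default, 10 Lloyd iterations) with per-cluster
variances and weights; starts run batched; a start collapsing onto a
near-zero-variance or empty component is frozen out, and a k with no
surviving start is dropped. Convergence is declared when the
log-likelihood improvement falls below 1e-8 relative to (1 + |loglik|)
or at 500 iterations — a relative criterion, since an absolute 1e-8 on
a many-thousand-term log-likelihood sits at float64 summation noise
and would always run to the cap.

## Windows and candidate calling

Non-overlapping 500-kb windows anchored at bp 1 per chromosome
(half-open spans; the origin is a convention choice — anchor at bp 1,
terminal partial windows kept and flagged). The LRH window statistic is
the f value, the share of score observations with z > 2.6; both
directions and alleles count as separate observations. XP-EHH windows
use max |z| with the sign of the peak attributing the window to
population A or B. Windows are grouped by SNP count in increments of
20, windows outside per-test bounds excluded (40–200 SNPs for LRH,
80–220 for XP-EHH), and within each group the empirical P of window i
is the fraction of windows with a strictly higher statistic;
candidates have P < 1%. Strict ">" is used in both the f-value
threshold and the empirical-P count, so ties favor candidacy. Windowed
mean F_ST uses the extreme-quantile rule instead: candidates sit at or
above the 97.5th percentile of window means. No randomness enters this
module, and empirical P values are rank statistics (invariant to
monotone transforms).

## Haplotype blocks

Pairs of SNPs are classified from phased gamete counts: |D'| is D
normalized by its frequency-dependent bound, and one-sided 95%
confidence bounds come from a normalized likelihood over a 101-point
|D'| grid (allele frequencies fixed at observed values, D's sign
fixed); strong LD requires upper bound > 0.98 and lower bound > 0.7,
historical recombination upper bound < 0.90, anything else is
uninformative. A block is a maximal span (≤ 500 kb by default) whose
endpoint pair is in strong LD and in which ≥ 95% of informative pairs
are strong; longer bp spans are claimed first, ties to the leftmost
start, accepted blocks cannot overlap. The auxiliary spacing/fraction
exceptions some tools apply to 2–4-SNP blocks are deliberately not
implemented — this is the pure 95% rule. With very weak pair
information (e.g. a boundary |D'| = 1 supported by two informative
gametes) the 95th-percentile upper bound can sit below the boundary
point estimate; such pairs are uninformative by construction.

## Quality control

QC operates on a diploid dosage table that allows missingness (phased
haplotype input is required to be complete). Order follows the scan's
conventions: individual missingness > 0.05, then SNP filters — MAF
< 0.05 (disabled for the between-population tests, which keep low-MAF
loci) and Hardy–Weinberg exact test P < 1e-6 (conventional direction;
mid-P off) — then indep-pairwise 50/5/0.2 LD pruning used only to feed
the relatedness test, and greedy removal of individuals in pi-hat
> 0.2 pairs (most-connected first, ties drop the later sample id).
pi-hat is the method-of-moments IBS-based estimate P(IBD=1)/2 +
P(IBD=2) with expected IBS probabilities at sample allele frequencies,
clamped and renormalized; small-sample bias corrections are not
applied, so ~1,000+ well-spaced SNPs are needed before the 0.2
threshold separates relatives from noise.

## The simulator and what passing tests show

The generator is a forward (not coalescent) Wright–Fisher simulation:
an ancestral pool whose per-site allele frequencies follow a
Beta(0.2, 0.2) spectrum (the U-shaped, low-MAF-heavy profile of chip
panels), a neutral burn-in (default 100 generations) that builds LD in
the ancestral population, then a clean split into two daughter
populations. Recombination is a Poisson number of crossovers per
meiosis (rate × length) with uniform breakpoints. Founder sites are
oversampled four-fold and the output thinned back to the requested
count of segregating sites, since drift fixes a share of them.

Defaults (n_anc = n_pop = 100 diploids, 16 post-split generations,
10 Mb, 1,000 SNPs, r = 1e-7/bp) are scaled so the *products* that
control the statistics match the data regime the scan targets: neutral
genome-wide mean theta_hat ≈ 0.04 (two recently diverged breeds), and
enough haplotype diversity that the combined EHH curve decays through
the marker-H band within 1 Mb. The per-bp recombination rate is
deliberately high relative to livestock genomes because population
sizes are scaled down ~100-fold; only N·r and t/N are meaningful.

Selection acts in population A only (symmetric selection is a config
option, off by default): genotype fitnesses 1, 1+s, 1+2s. The
favored-allele count trajectory is drawn first, from a dedicated RNG
stream, as the deterministic additive update
p* = p(1 + s(1 + p))/(1 + 2sp) followed by Binomial(2N) drift;
haplotype transmission is then conditioned on that trajectory
generation by generation (mismatched gametes are redrawn by rejection).
This makes the trajectory exactly reproducible by a scalar simulator
sharing the seed stream, which the test suite exploits as an
independent oracle. Population A's founding generation is conditioned
to carry exactly round(2N × sel_init_freq) favored copies; population
B founds from the ancestral pool unconditioned, and the selected column
is the segregating site nearest the requested position with ancestral
frequency closest to sel_init_freq. If a trajectory loses the allele,
up to max_retries fresh trajectories are drawn before failing. With
sel_stop_freq set, selection is sustained until the favored allele
first reaches that frequency and both populations are sampled at that
generation.

The sweep-recovery study conditions (also used by the acceptance
script): n_anc = 500, n_pop = 1000, 10 Mb / 700 SNPs, r = 2e-8,
s = 0.05 from ~5 founding copies, sampling when the favored allele
reaches 0.9 in A, replicates conditioned on final frequency < 0.3 in
B, selected site targeted at a window center. These choices make the
simulated sweep the object the methods are designed for — a hard sweep
observed at completion, with drift noise in windowed F_ST scaled below
the sweep's elevation and a hitchhiking footprint (~±200 kb at these
parameters) commensurate with the 500-kb windows. A sweep sampled long
after fixation, seeded on many standing haplotypes, or placed at a
window boundary is correspondingly harder to recover; the scan's power
against those scenarios is genuinely lower and nothing here hides
that.

What the generator does **not** emulate: new mutation (identity decays
only through recombination among founder mosaics), bottlenecks and
migration, varying recombination maps, genotyping error, and
ascertainment beyond the Beta-shaped founder spectrum. Passing tests
therefore demonstrate the statistics' internal correctness and their
behavior under idealized divergence-plus-sweep dynamics, not
performance on real chip data.

## Problem sizes in the test suite

Simulation-backed tests run at desk scale chosen once: neutral pairs of
100–200 diploids over 1–10 Mb; sweep recovery at the study conditions
above with 20 replicates; mixture recovery on 6,000 loci × 20
replicates; EHH oracle equivalence on 200 random panels up to 40 × 60.

## Known limitations

* The Gabriel scan enumerates candidate end-pairs within the span and
  is quadratic in SNPs per span; it is sized for chip-density desk
  runs, not sequence data.
* pi-hat omits PLINK's finite-sample bias corrections; with few or
  clustered SNPs it is noisy upward.
* The mixture decomposition assumes Gaussian components on theta_hat;
  heavy upper tails under strong divergence can inflate the selected k
  (AIC is liberal), which is why component *labels* use only the
  extreme means.
* marker-H selection uses the combined-core curve; scans in extreme-LD
  regions yield no REHH rather than an extrapolated one.
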