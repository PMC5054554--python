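"""Bayesian F_ST estimation with mixture-model decomposition.

Two steps.  First, per locus, allele frequencies in each population get
a Jeffreys-type Beta(1/2, 1/2) prior, so the posterior given counts
(n_A, n_a) is Beta(n_A + 1/2, n_a + 1/2).  S joint draws of the R group
frequencies are converted draw-by-draw into draws of the
differentiation parameter

    theta^(s) = [ sum_r p_r^2 - (sum_r p_r)^2 / R ]
                / [ ( R sum_r p_r - (sum_r p_r)^2 ) / R ]

and the posterior mean over valid draws is the point estimate
theta_hat.  The estimator is not range-constrained: individual draws
(and occasionally theta_hat) can be slightly negative; draws with a
degenerate denominator (all frequencies 0 or all 1) are skipped.

Second, the genome-wide distribution of theta_hat is decomposed with
univariate Gaussian mixtures fitted by EM, the component count chosen
by AIC (= -2 loglik + 2(3k - 1)); each locus is assigned to the
component with the largest conditional probability.  The components
with the highest and lowest means are candidate signals of directional
and balancing/purifying selection respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .genotype_io import HaplotypeSet, allele_counts

__all__ = [
    "sample_freq_posterior",
    "theta_draw",
    "theta_point",
    "bayes_fst_scan",
    "MixtureFit",
    "fit_theta_mixture",
    "assign_components",
]

DIRECTIONAL = "directional-candidate"
BALANCING = "balancing/purifying-candidate"


def sample_freq_posterior(
    n_A: int, n_a: int, S: int, rng: np.random.Generator | int
) -> np.ndarray:
    """S i.i.d. draws from the Beta(n_A + 1/2, n_a + 1/2) posterior."""
    if n_A < 0 or n_a < 0 or n_A + n_a == 0:
        raise ValueError("allele counts must be non-negative with a positive total")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.beta(n_A + 0.5, n_a + 0.5, size=S)


def theta_draw(p_draws: np.ndarray) -> np.ndarray:
    """Per-draw theta from an (S, R) array of group frequency draws.

    Draws whose denominator is zero (all R frequencies 0, or all 1)
    come back as NaN and should be skipped by the caller.
    """
    p = np.atleast_2d(np.asarray(p_draws, dtype=float))
    R = p.shape[1]
    if R < 2:
        raise ValueError("theta needs at least two groups")
    s1 = p.sum(axis=1)
    s2 = (p**2).sum(axis=1)
    num = s2 - s1**2 / R
    den = (R * s1 - s1**2) / R
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(den != 0.0, num / den, np.nan)
    return theta


def theta_point(theta_draws: np.ndarray) -> float:
    """Posterior mean over valid (finite) draws."""
    t = np.asarray(theta_draws, dtype=float)
    t = t[np.isfinite(t)]
    if t.size == 0:
        raise ValueError("no valid theta draws")
    return float(t.mean())


def bayes_fst_scan(
    hap_a: HaplotypeSet,
    hap_b: HaplotypeSet,
    S: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-SNP theta_hat over a shared map for two populations.

    Loci whose draws are all degenerate are excluded (theta_hat NaN).
    """
    if hap_a.n_snps != hap_b.n_snps or not np.array_equal(hap_a.positions, hap_b.positions):
        raise ValueError("populations must share a SNP map")
    rng = np.random.default_rng([int(seed), 41])
    ca = allele_counts(hap_a)
    cb = allele_counts(hap_b)
    m = hap_a.n_snps
    # vectorized: draw all loci at once per population
    pa = rng.beta(ca["n1"].to_numpy() + 0.5, ca["n0"].to_numpy() + 0.5, size=(S, m))
    pb = rng.beta(cb["n1"].to_numpy() + 0.5, cb["n0"].to_numpy() + 0.5, size=(S, m))
    s1 = pa + pb
    num = pa**2 + pb**2 - s1**2 / 2.0
    den = (2.0 * s1 - s1**2) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(den != 0.0, num / den, np.nan)
    with np.errstate(invalid="ignore"):
        theta_hat = np.nanmean(theta, axis=0)
    sm = hap_a.snp_map
    return pd.DataFrame(
        {
            "snp": np.arange(m),
            "id": sm["id"],
            "chrom": sm["chrom"],
            "pos": sm["pos"].astype(int),
            "theta_hat": theta_hat,
        }
    )


# ---------------------------------------------------------------------------
# Gaussian mixture by EM, model choice by AIC


@dataclass
class MixtureFit:
    """A fitted univariate Gaussian mixture (Results-style object)."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    aic: float
    responsibilities: np.ndarray
    n_iter: int
    converged: bool
    model_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> pd.DataFrame:
        """Component table: weight, mean, SD, locus share."""
        assign = self.responsibilities.argmax(axis=1)
        return pd.DataFrame(
            {
                "component": np.arange(self.k),
                "weight": self.weights,
                "mean": self.means,
                "sd": np.sqrt(self.variances),
                "n_assigned": np.bincount(assign, minlength=self.k),
            }
        )


def _em_batched(
    x: np.ndarray,
    mu0: np.ndarray,
    var0: np.ndarray,
    w0: np.ndarray,
    tol: float,
    max_iter: int,
    var_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray, int, bool] | None:
    """EM over a batch of starts; returns the best non-degenerate run.

    ``mu0``/``var0``/``w0`` are ``(n_starts, k)``; all starts iterate
    together (vectorized over the start axis).  A start whose components
    collapse (near-zero variance or empty responsibility mass) is frozen
    out; returns None when every start degenerates.
    """
    n = x.size
    n_starts, k = mu0.shape
    mu = mu0.astype(float).copy()
    var = np.maximum(var0.astype(float), var_floor)
    w = w0.astype(float).copy()
    alive = np.ones(n_starts, dtype=bool)
    prev_ll = np.full(n_starts, -np.inf)
    ll = prev_ll.copy()
    xc = x[None, :, None]  # (1, n, 1)
    converged = np.zeros(n_starts, dtype=bool)
    it = 0
    for it in range(1, max_iter + 1):
        log_comp = (
            (np.log(w) - 0.5 * np.log(2 * np.pi * var))[:, None, :]
            - 0.5 * (xc - mu[:, None, :]) ** 2 / var[:, None, :]
        )  # (n_starts, n, k)
        m = log_comp.max(axis=2, keepdims=True)
        np.exp(log_comp - m, out=log_comp)
        resp = log_comp  # reused buffer
        se = resp.sum(axis=2, keepdims=True)
        ll = (m[:, :, 0] + np.log(se[:, :, 0])).sum(axis=1)
        resp /= se
        nk = resp.sum(axis=1)  # (n_starts, k)
        dead = (nk < 1e-10).any(axis=1)
        safe_nk = np.where(nk < 1e-10, 1.0, nk)
        w = nk / n
        mu_new = (resp * xc).sum(axis=1) / safe_nk
        var_new = (resp * (xc - mu_new[:, None, :]) ** 2).sum(axis=1) / safe_nk
        dead |= (var_new < var_floor).any(axis=1)
        alive &= ~dead
        if not alive.any():
            return None
        mu = np.where(dead[:, None], mu, mu_new)
        var = np.where(dead[:, None], var, np.maximum(var_new, var_floor))
        # relative criterion: an absolute 1e-8 is below the resolution
        # of a many-term loglik sum and would always hit the cap
        converged = alive & (np.abs(ll - prev_ll) < tol * (1.0 + np.abs(ll)))
        if (converged | ~alive).all():
            break
        prev_ll = ll
    ll = np.where(alive, ll, -np.inf)
    best = int(np.argmax(ll))
    # final E-step for the winner's responsibilities
    log_comp = (
        np.log(w[best])[None, :]
        - 0.5 * np.log(2 * np.pi * var[best])[None, :]
        - 0.5 * (x[:, None] - mu[best][None, :]) ** 2 / var[best][None, :]
    )
    norm = logsumexp(log_comp, axis=1)
    resp = np.exp(log_comp - norm[:, None])
    return w[best], mu[best], var[best], float(norm.sum()), resp, it, bool(converged[best])


def fit_theta_mixture(
    theta_hats: np.ndarray,
    k_range: range | tuple[int, int] = (1, 8),
    seed: int = 0,
    n_starts: int = 3,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureFit:
    """Fit Gaussian mixtures for each k and keep the smallest-AIC model.

    For each k, ``n_starts`` initializations are tried (the first from
    equally spaced quantiles of the data, the rest random data points);
    the best run by log-likelihood represents that k.  Runs collapsing
    onto a degenerate (near-zero-variance or empty) component are
    restarted; if every start for some k degenerates, that k is
    dropped.  AIC = -2 loglik + 2(3k - 1).
    """
    x = np.asarray(theta_hats, dtype=float)
    x = x[np.isfinite(x)]
    if isinstance(k_range, range):
        ks = list(k_range)
    else:
        ks = list(range(k_range[0], k_range[1] + 1))
    if x.size < 10 * max(ks):
        raise ValueError(f"need at least {10 * max(ks)} loci for k up to {max(ks)}")
    rng = np.random.default_rng([int(seed), 43])
    var_floor = max(x.var() * 1e-10, 1e-300)

    def kmeans_init(mu0: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """A few Lloyd iterations in 1-D; moments per cluster seed EM."""
        mu_k = np.sort(mu0.astype(float))
        kk = mu_k.size
        assign = np.zeros(x.size, dtype=int)
        for _ in range(10):
            assign = np.argmin(np.abs(x[:, None] - mu_k[None, :]), axis=1)
            for c in range(kk):
                sel = assign == c
                if sel.any():
                    mu_k[c] = x[sel].mean()
        var_k = np.full(kk, x.var())
        w_k = np.full(kk, 1.0 / kk)
        for c in range(kk):
            sel = assign == c
            if sel.sum() >= 2:
                var_k[c] = x[sel].var()
                w_k[c] = sel.mean()
        w_k /= w_k.sum()
        return mu_k, var_k, w_k

    results: list[MixtureFit] = []
    rows = []
    for k in ks:
        mus, vars_, ws = [], [], []
        for s in range(n_starts):
            if s == 0:
                mu0 = np.quantile(x, (np.arange(k) + 0.5) / k)
            else:
                mu0 = rng.choice(x, size=k, replace=False)
            m_i, v_i, w_i = kmeans_init(mu0)
            mus.append(m_i)
            vars_.append(v_i)
            ws.append(w_i)
        run = _em_batched(
            x, np.array(mus), np.array(vars_), np.array(ws), tol, max_iter, var_floor
        )
        if run is None:
            continue
        w, mu, var, ll, resp, it, conv = run
        aic = -2.0 * ll + 2.0 * (3 * k - 1)
        rows.append({"k": k, "loglik": ll, "aic": aic})
        results.append(
            MixtureFit(
                k=k,
                weights=w,
                means=mu,
                variances=var,
                loglik=ll,
                aic=aic,
                responsibilities=resp,
                n_iter=it,
                converged=conv,
            )
        )
    if not results:
        raise RuntimeError("every mixture fit degenerated")
    table = pd.DataFrame(rows)
    winner = min(results, key=lambda r: r.aic)
    winner.model_table = table
    return winner


def assign_components(fit: MixtureFit) -> tuple[np.ndarray, dict[int, str]]:
    """Argmax-responsibility component per locus, plus labels for the
    extreme components.

    Ties go to the lower-index component (argmax convention).  The
    component with the highest mean is labelled directional-candidate,
    the one with the lowest mean balancing/purifying-candidate.
    """
    assign = fit.responsibilities.argmax(axis=1)
    labels = {
        int(np.argmax(fit.means)): DIRECTIONAL,
        int(np.argmin(fit.means)): BALANCING,
    }
    return assign, labels
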