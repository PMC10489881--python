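"""MCMC convergence and model-fit diagnostics.

Implements the model-checking toolkit used alongside the hierarchical
fits: split-R-hat (between/within chain-variance form), rank-normalized
bulk effective sample size with Geyer's initial-monotone truncation,
tail ESS from the 5%/95% exceedance indicators, Fisher-Pearson-skew
posterior predictive checks, and Pareto-smoothed importance-sampling
leave-one-out cross-validation (PSIS-LOO) with a Zhang-Stephens
generalized-Pareto tail fit.

Conventions: R-hat below ~1.1 and bulk/tail ESS above ~1000 indicate
convergence; Pareto k below 0.5 indicates a reliable LOO estimate for
that observation (k above 0.7 is reported as problematic).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp, ndtri

__all__ = [
    "split_rhat",
    "ess",
    "fisher_pearson_skew",
    "posterior_predictive",
    "psis_loo",
    "PPCResult",
    "DiagnosticsReport",
]


def _split_chains(x: np.ndarray) -> np.ndarray:
    """Split each chain in half: (C, N) -> (2C, N//2)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[1] // 2
    return np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)


def split_rhat(x: np.ndarray, return_flag: bool = False):
    """Split-R-hat over (chains x iterations) draws of one parameter.

    Constant draws across all chains return 1.0 by convention (with the
    degeneracy flag if requested).
    """
    z = _split_chains(x)
    if z.shape[0] < 4 or z.shape[1] < 2:
        raise ValueError("need >= 2 chains and >= 4 iterations")
    if np.ptp(z) == 0.0:
        return (1.0, True) if return_flag else 1.0
    n = z.shape[1]
    w = float(np.mean(np.var(z, axis=1, ddof=1)))
    b = n * float(np.var(np.mean(z, axis=1), ddof=1))
    rhat = float(np.sqrt(((n - 1) / n * w + b / n) / w))
    return (rhat, False) if return_flag else rhat


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    """Pooled fractional ranks mapped through the normal quantile function."""
    shape = x.shape
    flat = x.reshape(-1)
    ranks = np.empty_like(flat)
    ranks[np.argsort(flat, kind="stable")] = np.arange(1, flat.size + 1)
    return ndtri((ranks - 3.0 / 8.0) / (flat.size + 0.25)).reshape(shape)


def _ess_from_chains(z: np.ndarray) -> float:
    """ESS of (chains x iters) draws via FFT autocovariance and Geyer's
    initial monotone positive pair sequence."""
    c, n = z.shape
    if np.ptp(z) == 0.0:
        return float(c * n)
    chain_means = z.mean(axis=1)
    zc = z - chain_means[:, None]
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(zc, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n
    w = float(np.mean(acov[:, 0]) * n / (n - 1))
    var_plus = w * (n - 1) / n
    if c > 1:
        var_plus += float(np.var(chain_means, ddof=1))
    mean_acov = acov.mean(axis=0)
    rho = 1.0 - (w - mean_acov) / var_plus  # rho[0] may be slightly < 1
    # Geyer pairs P_t = rho_{2t} + rho_{2t+1}: truncate at the first
    # non-positive pair, then force the sequence monotone non-increasing
    n_pairs = (n - 1) // 2
    pair = rho[: 2 * n_pairs].reshape(-1, 2).sum(axis=1)
    pos = pair > 0.0
    stop = int(np.argmin(pos)) if not pos.all() else pair.size
    pair = np.minimum.accumulate(pair[:stop]) if stop > 0 else pair[:0]
    tau = -1.0 + 2.0 * float(np.sum(np.clip(pair, 0.0, None)))
    tau = max(tau, 1.0 / np.log10(c * n + 10.0))
    return float(c * n / tau)


def ess(x: np.ndarray) -> tuple[float, float]:
    """(bulk, tail) effective sample size of (chains x iterations) draws.

    Bulk ESS uses rank-normalized draws; tail ESS is the minimum ESS of
    the 5% and 95% exceedance indicators.
    """
    z = _split_chains(x)
    if z.shape[0] < 4 or z.shape[1] < 2:
        raise ValueError("need >= 2 chains and >= 4 iterations")
    if np.ptp(z) == 0.0:
        return float(z.size), float(z.size)
    bulk = _ess_from_chains(_rank_normalize(z))
    q05, q95 = np.quantile(z, [0.05, 0.95])
    tails = []
    for ind in ((z <= q05), (z >= q95)):
        ind = ind.astype(float)
        tails.append(
            _ess_from_chains(ind) if np.ptp(ind) > 0 else float(ind.size)
        )
    return bulk, float(min(tails))


def fisher_pearson_skew(sample) -> float:
    """Unadjusted Fisher-Pearson skewness g1 = m3 / m2^(3/2)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    m2 = float(np.mean(xc**2))
    if m2 == 0.0:
        raise ValueError("zero variance sample has undefined skewness")
    return float(np.mean(xc**3) / m2**1.5)


# ---------------------------------------------------------------------------
# posterior predictive check


@dataclass
class PPCResult:
    observed_skew: float
    replicate_skews: np.ndarray
    tail_prob: float  # two-sided position of the observed statistic

    def to_dict(self) -> dict:
        return {
            "observed_skew": self.observed_skew,
            "tail_prob": self.tail_prob,
            "n_replicates": int(self.replicate_skews.size),
        }


def posterior_predictive(
    draws, data, spec, ndraws: int = 1000, seed: int = 0
) -> PPCResult:
    """Skewness-based posterior predictive check.

    For each of ``ndraws`` posterior draws a full replicated response
    vector is simulated from the fitted family, and the Fisher-Pearson
    skew of each replicate is compared with the observed skew; a
    two-sided tail probability near 0 or 1 signals badly modeled skew.
    """
    fam = spec.make_family()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    flat = draws.draws.reshape(-1, draws.draws.shape[2])
    take = min(ndraws, flat.shape[0])
    idx = np.linspace(0, flat.shape[0] - 1, take).astype(int)
    p = data.p
    skews = np.empty(take)
    for i, s in enumerate(idx):
        beta = flat[s, :p]
        log_aux = flat[s, p]
        eta = data.X @ beta
        if spec.include_random_intercept and data.n_groups:
            eta = eta + flat[s, p + 2 :][data.group]
        rep = fam.simulate(rng, eta, log_aux)
        skews[i] = fisher_pearson_skew(rep)
    obs = fisher_pearson_skew(data.y)
    p_hi = float(np.mean(skews >= obs))
    p_lo = float(np.mean(skews <= obs))
    tail = min(1.0, 2.0 * min(p_hi, p_lo))
    return PPCResult(observed_skew=obs, replicate_skews=skews, tail_prob=tail)


# ---------------------------------------------------------------------------
# PSIS-LOO


def _gpd_fit(excess: np.ndarray) -> tuple[float, float]:
    """Zhang & Stephens (2009) profile-likelihood fit of the generalized
    Pareto shape k and scale sigma to positive excesses."""
    x = np.sort(excess)
    n = x.size
    m = 30 + int(np.floor(np.sqrt(n)))
    j = np.arange(1, m + 1)
    x_quart = x[int(np.floor(n / 4.0 + 0.5)) - 1]
    b = 1.0 / x[-1] + (1.0 - np.sqrt(m / (j - 0.5))) / (3.0 * x_quart)
    k_j = -np.mean(np.log1p(-b[:, None] * x[None, :]), axis=1)
    log_lik = n * (np.log(b / k_j) + k_j - 1.0)
    weights = np.exp(log_lik - logsumexp(log_lik))
    b_hat = float(np.sum(weights * b))
    k_hat = float(-np.mean(np.log1p(-b_hat * x)))
    sigma = k_hat / b_hat
    # weak regularization of k toward 0.5 (10 pseudo-observations)
    k_hat = (n * k_hat + 5.0) / (n + 10.0)
    return k_hat, sigma


def psis_loo(pointwise: np.ndarray) -> tuple[float, np.ndarray]:
    """PSIS-LOO from an (S draws x n observations) log-likelihood matrix.

    Returns the expected log pointwise predictive density ``elpd_loo``
    and the per-observation Pareto-k tail-shape estimates.
    """
    ll = np.asarray(pointwise, dtype=float)
    if ll.ndim != 2:
        raise ValueError("expected a draws x observations matrix")
    s, n = ll.shape
    if s < 400:
        raise ValueError("PSIS needs at least 400 draws")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log-likelihoods")
    m_tail = int(np.ceil(min(0.2 * s, 3.0 * np.sqrt(s))))
    if m_tail < 5:
        raise ValueError("tail too short for the generalized-Pareto fit")
    ks = np.empty(n)
    elpd_i = np.empty(n)
    for i in range(n):
        lw = -ll[:, i]
        lw = lw - lw.max()
        order = np.argsort(lw)
        tail_ix = order[-m_tail:]
        cutoff = lw[order[-m_tail - 1]]
        w_tail = np.exp(lw[tail_ix])
        excess = w_tail - np.exp(cutoff)
        if np.ptp(excess) <= 0.0:
            ks[i] = -np.inf
        else:
            k, sigma = _gpd_fit(excess[excess > 0])
            ks[i] = k
            if np.isfinite(k):
                # replace tail weights by expected GPD order statistics
                q = (np.arange(1, m_tail + 1) - 0.5) / m_tail
                if abs(k) < 1e-12:
                    quant = -sigma * np.log1p(-q)
                else:
                    quant = sigma / k * (np.power(1.0 - q, -k) - 1.0)
                smoothed = np.log(np.exp(cutoff) + quant)
                # truncate at the raw maximum
                smoothed = np.minimum(smoothed, 0.0)
                lw[tail_ix[np.argsort(lw[tail_ix], kind="stable")]] = smoothed
        lw_norm = lw - logsumexp(lw)
        elpd_i[i] = logsumexp(lw_norm + ll[:, i])
    return float(np.sum(elpd_i)), ks


# ---------------------------------------------------------------------------
# aggregated report


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence metrics plus model-level fit checks."""

    rhat: dict[str, float]
    ess_bulk: dict[str, float]
    ess_tail: dict[str, float]
    ppc: PPCResult | None = None
    elpd_loo: float | None = None
    pareto_k: np.ndarray | None = None

    @property
    def n_k_above_05(self) -> int:
        return 0 if self.pareto_k is None else int(np.sum(self.pareto_k > 0.5))

    @property
    def n_k_above_07(self) -> int:
        return 0 if self.pareto_k is None else int(np.sum(self.pareto_k > 0.7))

    def to_dict(self) -> dict:
        return {
            "rhat": self.rhat,
            "ess_bulk": self.ess_bulk,
            "ess_tail": self.ess_tail,
            "ppc": None if self.ppc is None else self.ppc.to_dict(),
            "elpd_loo": self.elpd_loo,
            "pareto_k_above_0.5": self.n_k_above_05,
            "pareto_k_above_0.7": self.n_k_above_07,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
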