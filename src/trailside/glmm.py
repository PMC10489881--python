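"""Hierarchical disturbance x elevation models and their MCMC sampler.

The model, fit separately for percent cover and for each species-by-trait
combination, is

    response ~ disturbance * elevation + (1 | transect pair)

with a negative binomial family (log mean link, log shape link) for
rounded height/diameter and a Beta family (logit mean link by default,
log precision link) for relative reproduction and percent cover.  The
transect-pair random intercept absorbs the shared location of each
trail-side / off-trail pair.

Priors are weakly informative and configurable: Student-t(3, 0, 10) on
each fixed effect, half-Student-t(3, 0, 2.5) on the random-intercept sd,
and Normal(0, 2.5^2) on the log auxiliary parameter (NB shape or Beta
precision).  Inference is by an adaptive random-walk Metropolis-within-
Gibbs sampler: blocks (fixed effects, component-wise), (random
intercepts, group-wise), (log sd), (log auxiliary), with proposal scales
adapted during warmup toward a 20-40% acceptance window and frozen
afterwards.  Internally the non-intercept design columns are centred and
scaled for sampler stability; reported draws are back-transformed exactly
to the raw scale (elevation in metres), so coefficients are comparable to
per-metre estimates.

An effect is inferred for a coefficient when its equal-tailed 95%
credible interval excludes zero.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .families import Family, get_family

__all__ = [
    "PriorConfig",
    "ModelSpec",
    "GLMMData",
    "PosteriorDraws",
    "FitSummary",
    "build_model_data",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "sample_posterior",
    "summarize_fit",
    "pointwise_loglik",
]

FIXED_EFFECT_NAMES = ["intercept", "b_disturbance", "b_elevation", "b_interaction"]


# ---------------------------------------------------------------------------
# specification and data containers


@dataclass(frozen=True)
class PriorConfig:
    """Prior hyperparameters; scales are on the raw coefficient scale."""

    beta_prior: str = "student_t"  # or "normal"
    beta_df: float = 3.0
    beta_scale: float = 10.0
    sigma_df: float = 3.0
    sigma_scale: float = 2.5
    aux_scale: float = 2.5


@dataclass(frozen=True)
class ModelSpec:
    """Choice of response, family, links and priors for one model."""

    response: str
    family: str  # negative_binomial | beta | normal
    link: str = "default"  # beta mean link: logit (default) or log
    priors: PriorConfig = field(default_factory=PriorConfig)
    include_random_intercept: bool = True
    standardize: bool = True

    def make_family(self) -> Family:
        link = self.link
        if link == "default":
            link = "logit"
        return get_family(self.family, link=link)


@dataclass
class GLMMData:
    """Design bundle for one model fit.

    ``X`` keeps the raw-scale columns (leading intercept column of ones);
    ``group`` holds contiguous 0-based transect-pair indices.
    """

    y: np.ndarray
    X: np.ndarray
    colnames: list[str]
    group: np.ndarray | None = None
    group_labels: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.y.shape[0])

    @property
    def n_groups(self) -> int:
        return 0 if self.group is None else len(self.group_labels)

    @property
    def p(self) -> int:
        return int(self.X.shape[1])

    def validate(self) -> None:
        if self.X.shape[0] != self.n:
            raise ValueError("X and y row counts differ")
        if not np.all(np.isfinite(self.y)) or not np.all(np.isfinite(self.X)):
            raise ValueError("missing or non-finite values in model data")
        if self.group is not None:
            if self.group.shape[0] != self.n:
                raise ValueError("group index length mismatch")
            if self.group.min() < 0 or self.group.max() >= self.n_groups:
                raise ValueError("group indices must be contiguous 0..J-1")


def build_model_data(table: pd.DataFrame, spec: ModelSpec) -> GLMMData:
    """Assemble y, the [1, D, E, D*E] design matrix and pair indices.

    The response column must already be prepared for its family
    (``round_for_nb`` for NB sizes, ``adjust_unit_interval`` for Beta
    proportions); violations raise with an instruction.  One model's data
    must hold a single species (percent cover uses all quadrats).
    """
    if spec.response not in table.columns:
        raise KeyError(f"response column {spec.response!r} not in table")
    if "species" in table.columns and table["species"].nunique() > 1:
        raise ValueError("one model's data must contain exactly one species")
    sub = table.dropna(subset=[spec.response]).reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no usable rows for response {spec.response!r}")
    y = np.asarray(sub[spec.response], dtype=float)
    spec.make_family().validate_response(y)
    d = np.asarray(sub["disturbed"], dtype=float)
    e = np.asarray(sub["elevation_m"], dtype=float)
    if np.ptp(d) == 0.0:
        warnings.warn(
            "disturbance indicator is constant: its coefficient is "
            "unidentifiable and will follow the prior",
            UserWarning,
            stacklevel=2,
        )
    X = np.column_stack([np.ones_like(d), d, e, d * e])
    group = None
    labels: list[str] = []
    if spec.include_random_intercept:
        codes, uniques = pd.factorize(sub["pair_id"], sort=True)
        group = codes.astype(np.int64)
        labels = [str(u) for u in uniques]
    return GLMMData(y=y, X=X, colnames=list(FIXED_EFFECT_NAMES), group=group,
                    group_labels=labels)


# ---------------------------------------------------------------------------
# parameter vector layout (raw scale):
#   [beta_0..beta_{p-1}, log_aux, (log_sigma_pair, u_1..u_J)]


def param_names(data: GLMMData, spec: ModelSpec) -> list[str]:
    names = list(data.colnames)
    names.append(spec.make_family().aux_name)
    if spec.include_random_intercept and data.n_groups:
        names.append("log_sigma_pair")
        names.extend(f"u[{lab}]" for lab in data.group_labels)
    return names


def _unpack(params: np.ndarray, data: GLMMData, spec: ModelSpec):
    p = data.p
    beta = params[:p]
    log_aux = params[p]
    if spec.include_random_intercept and data.n_groups:
        log_sigma = params[p + 1]
        u = params[p + 2 : p + 2 + data.n_groups]
    else:
        log_sigma, u = None, None
    return beta, log_aux, log_sigma, u


def log_likelihood(params, data: GLMMData, spec: ModelSpec):
    """Total and pointwise log-likelihood at a raw-scale parameter vector."""
    params = np.asarray(params, dtype=float)
    beta, log_aux, _, u = _unpack(params, data, spec)
    fam = spec.make_family()
    if data.n == 0:
        return 0.0, np.zeros(0)
    eta = data.X @ beta
    if u is not None:
        eta = eta + u[data.group]
    pointwise = fam.loglik_pointwise(data.y, eta, log_aux)
    return float(np.sum(pointwise)), pointwise


def _t_logpdf(x, df, scale):
    x = np.asarray(x, dtype=float)
    c = (
        gammaln((df + 1.0) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
    )
    return c - (df + 1.0) / 2.0 * np.log1p((x / scale) ** 2 / df)


def _half_t_logpdf(x, df, scale):
    # density of |T|, x >= 0
    return np.log(2.0) + _t_logpdf(x, df, scale)


def _normal_logpdf(x, sd):
    x = np.asarray(x, dtype=float)
    return -0.5 * (x / sd) ** 2 - np.log(sd) - 0.5 * np.log(2.0 * np.pi)


def log_prior(params, data: GLMMData, spec: ModelSpec) -> float:
    """Log prior density, including the Jacobian for log-scale sigma."""
    params = np.asarray(params, dtype=float)
    beta, log_aux, log_sigma, u = _unpack(params, data, spec)
    pc = spec.priors
    if pc.beta_prior == "student_t":
        lp = float(np.sum(_t_logpdf(beta, pc.beta_df, pc.beta_scale)))
    elif pc.beta_prior == "normal":
        lp = float(np.sum(_normal_logpdf(beta, pc.beta_scale)))
    else:
        raise ValueError(f"unknown beta prior {pc.beta_prior!r}")
    lp += float(_normal_logpdf(log_aux, pc.aux_scale))
    if log_sigma is not None:
        sigma = np.exp(log_sigma)
        # half-t prior on sigma plus the log-scale Jacobian d sigma/d log
        lp += float(_half_t_logpdf(sigma, pc.sigma_df, pc.sigma_scale)) + log_sigma
        lp += float(np.sum(_normal_logpdf(u, sigma)))
    return lp


def log_posterior(params, data: GLMMData, spec: ModelSpec) -> float:
    total, _ = log_likelihood(params, data, spec)
    return total + log_prior(params, data, spec)


# ---------------------------------------------------------------------------
# sampler


@dataclass
class PosteriorDraws:
    """Post-warmup draws, back-transformed to the raw coefficient scale.

    ``draws`` has shape (chains, kept_iterations, n_parameters) with the
    parameter order of ``names``.
    """

    draws: np.ndarray
    names: list[str]
    seed: int
    iterations: int
    warmup: int
    accept_rates: dict[str, float]

    @property
    def chains(self) -> int:
        return self.draws.shape[0]

    @property
    def kept(self) -> int:
        return self.draws.shape[1]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def get(self, name: str) -> np.ndarray:
        """(chains, kept) draws of one parameter."""
        return self.draws[:, :, self.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)


def _design_transform(X: np.ndarray, colnames: list[str]):
    """Internal sampling design and the exact raw-scale back-transform.

    For the canonical [1, D, E, D*E] design the sampler works on
    [1, D - mean(D), z, (D - mean(D)) * z] with z = (E - mean) / sd: these
    columns are near-orthogonal (the raw product column D*E is almost
    collinear with D because elevation varies little relative to its
    mean), which is what lets a component-wise random walk mix.  For any
    other design each non-intercept column is centred and scaled.  Returns
    (Xs, T) with raw_beta = T @ beta_sampling, an exact linear map.
    """
    n, p = X.shape
    if list(colnames) == FIXED_EFFECT_NAMES and p == 4:
        d_col, e_col = X[:, 1], X[:, 2]
        m_d = float(d_col.mean()) if np.ptp(d_col) > 0 else 0.0
        m_e = float(e_col.mean())
        s_e = float(e_col.std()) or 1.0
        Xs = np.empty_like(X)
        Xs[:, 0] = 1.0
        Xs[:, 1] = d_col - m_d
        Xs[:, 2] = (e_col - m_e) / s_e
        Xs[:, 3] = Xs[:, 1] * Xs[:, 2]
        T = np.array(
            [
                [1.0, -m_d, -m_e / s_e, m_d * m_e / s_e],
                [0.0, 1.0, 0.0, -m_e / s_e],
                [0.0, 0.0, 1.0 / s_e, -m_d / s_e],
                [0.0, 0.0, 0.0, 1.0 / s_e],
            ]
        )
        return Xs, T
    Xs = X.copy()
    T = np.eye(p)
    for j in range(1, p):
        col = X[:, j]
        m, s = float(col.mean()), float(col.std())
        if s == 0.0:
            continue  # degenerate column: leave raw (coefficient prior-driven)
        Xs[:, j] = (col - m) / s
        T[j, j] = 1.0 / s
        T[0, j] = -m / s
    return Xs, T


class _Adapt:
    """Robbins-Monro proposal-scale adaptation toward ~30% acceptance."""

    def __init__(self, n, init_step=0.2, window=50):
        self.log_step = np.full(n, np.log(init_step))
        self.accepts = np.zeros(n)
        self.attempts = np.zeros(n)
        self.window = window
        self.frozen = False
        self.total_accepts = np.zeros(n)
        self.total_attempts = np.zeros(n)

    @property
    def step(self):
        return np.exp(self.log_step)

    def record(self, accepted):
        self.attempts += 1
        self.accepts += accepted
        self.total_attempts += 1
        self.total_accepts += accepted
        if not self.frozen and self.attempts[0] >= self.window:
            rate = self.accepts / self.attempts
            self.log_step = np.clip(self.log_step + (rate - 0.3), -12.0, 4.0)
            self.accepts[:] = 0.0
            self.attempts[:] = 0.0

    def rate(self):
        with np.errstate(invalid="ignore"):
            return float(np.mean(self.total_accepts / self.total_attempts))


def sample_posterior(
    data: GLMMData,
    spec: ModelSpec,
    chains: int = 3,
    iterations: int = 5000,
    warmup: int = 1000,
    seed: int = 0,
    fix_aux: float | None = None,
) -> PosteriorDraws:
    """Draw from the posterior with adaptive Metropolis-within-Gibbs.

    ``iterations`` is the total per chain; the first ``warmup`` iterations
    adapt the proposal scales and are discarded.  ``fix_aux`` pins the
    auxiliary parameter (used by validation harnesses with known noise).
    Given the same seed the draws are identical.
    """
    data.validate()
    if chains < 2:
        raise ValueError("at least 2 chains are required for diagnostics")
    if warmup >= iterations:
        raise ValueError("warmup must be smaller than iterations")
    fam = spec.make_family()
    fam.validate_response(data.y)
    pc = spec.priors
    use_ri = spec.include_random_intercept and data.n_groups > 0
    y, g = data.y, data.group
    J = data.n_groups if use_ri else 0
    p = data.p

    if spec.standardize:
        Xs, T = _design_transform(data.X, data.colnames)
    else:
        Xs, T = data.X, np.eye(p)

    def beta_logprior(beta_s):
        raw = T @ beta_s
        if pc.beta_prior == "student_t":
            return float(np.sum(_t_logpdf(raw, pc.beta_df, pc.beta_scale)))
        return float(np.sum(_normal_logpdf(raw, pc.beta_scale)))

    # initialization: 'init = 0' for the Beta family (cover / reproduction
    # models), data-informed for NB and normal
    def initial_state():
        beta_s = np.zeros(p)
        if spec.family == "beta":
            log_aux = 0.0
            log_sigma = 0.0
        else:
            eta0, log_aux = fam.default_init(y)
            beta_s[0] = eta0
            log_sigma = float(np.log(0.3))
        if fix_aux is not None:
            log_aux = float(fix_aux)
        u = np.zeros(J)
        return beta_s, log_aux, log_sigma, u

    # columns constant within every pair (the intercept, and elevation,
    # which is shared by the two transects of a pair) are exactly
    # confounded with the random intercepts; likelihood-invariant
    # translation moves along those ridges are needed for mixing
    ridge_cols: list[tuple[int, np.ndarray]] = []
    if use_ri:
        for j in range(p):
            col = Xs[:, j]
            mins = np.full(J, np.inf)
            maxs = np.full(J, -np.inf)
            np.minimum.at(mins, g, col)
            np.maximum.at(maxs, g, col)
            if np.all(maxs - mins == 0.0):
                ridge_cols.append((j, mins.copy()))

    kept = iterations - warmup
    n_par = p + 1 + (1 + J if use_ri else 0)
    out = np.empty((chains, kept, n_par))
    accept_info: dict[str, float] = {}
    seeds = np.random.SeedSequence(int(seed)).spawn(chains)

    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        beta_s, log_aux, log_sigma, u = initial_state()
        eta_base = Xs @ beta_s
        eta = eta_base + (u[g] if use_ri else 0.0)
        ll_pt = fam.loglik_pointwise(y, eta, log_aux)
        ll = float(np.sum(ll_pt))
        if not np.isfinite(ll):
            raise RuntimeError(
                "non-finite posterior at initialization; rescale the data "
                "or try another seed"
            )
        lp_beta = beta_logprior(beta_s)

        ad_beta = _Adapt(p)
        ad_u = _Adapt(max(J, 1))
        ad_scalar = _Adapt(2, init_step=0.3)  # [log_sigma, log_aux]
        ad_ridge = _Adapt(max(len(ridge_cols), 1), init_step=0.3)

        for it in range(iterations):
            if it == warmup:
                ad_beta.frozen = ad_u.frozen = ad_scalar.frozen = True

            # --- fixed effects, component-wise random walk
            acc_b = np.zeros(p)
            steps_b = ad_beta.step
            for j in range(p):
                prop = beta_s.copy()
                prop[j] += steps_b[j] * rng.standard_normal()
                delta = prop[j] - beta_s[j]
                eta_p = eta + Xs[:, j] * delta
                ll_pt_p = fam.loglik_pointwise(y, eta_p, log_aux)
                ll_p = float(np.sum(ll_pt_p))
                lp_p = beta_logprior(prop)
                if np.log(rng.uniform()) < ll_p - ll + lp_p - lp_beta:
                    beta_s, eta, ll_pt, ll, lp_beta = prop, eta_p, ll_pt_p, ll_p, lp_p
                    eta_base = eta_base + Xs[:, j] * delta
                    acc_b[j] = 1.0
            ad_beta.record(acc_b)

            if use_ri:
                # --- random intercepts, all groups at once (independent
                # accept/reject: the likelihood factorizes by group)
                sigma = np.exp(log_sigma)
                u_p = u + ad_u.step * rng.standard_normal(J)
                eta_p = eta_base + u_p[g]
                ll_pt_p = fam.loglik_pointwise(y, eta_p, log_aux)
                d_ll = np.bincount(g, weights=ll_pt_p - ll_pt, minlength=J)
                d_pr = 0.5 * (u**2 - u_p**2) / sigma**2
                acc = np.log(rng.uniform(size=J)) < d_ll + d_pr
                if acc.any():
                    u = np.where(acc, u_p, u)
                    eta = eta_base + u[g]
                    ll_pt = np.where(acc[g], ll_pt_p, ll_pt)
                    ll = float(np.sum(ll_pt))
                ad_u.record(acc.astype(float))

                # --- log sigma: prior-only conditional (no likelihood term)
                prop_ls = log_sigma + ad_scalar.step[0] * rng.standard_normal()
                cur = (
                    _half_t_logpdf(np.exp(log_sigma), pc.sigma_df, pc.sigma_scale)
                    + log_sigma
                    + float(np.sum(_normal_logpdf(u, np.exp(log_sigma))))
                )
                new = (
                    _half_t_logpdf(np.exp(prop_ls), pc.sigma_df, pc.sigma_scale)
                    + prop_ls
                    + float(np.sum(_normal_logpdf(u, np.exp(prop_ls))))
                )
                acc_s = np.log(rng.uniform()) < new - cur
                if acc_s:
                    log_sigma = prop_ls

                # --- ridge translations: shift a group-constant fixed
                # effect and counter-shift the random intercepts; the
                # likelihood is exactly unchanged, only priors decide
                sigma = np.exp(log_sigma)
                acc_r = np.zeros(len(ridge_cols))
                for r_ix, (j, v) in enumerate(ridge_cols):
                    delta = ad_ridge.step[r_ix] * rng.standard_normal()
                    prop = beta_s.copy()
                    prop[j] += delta
                    u_p = u - delta * v
                    lp_p = beta_logprior(prop)
                    d_pr = float(np.sum(0.5 * (u**2 - u_p**2) / sigma**2))
                    if np.log(rng.uniform()) < lp_p - lp_beta + d_pr:
                        eta_base = eta_base + Xs[:, j] * delta
                        beta_s, u, lp_beta = prop, u_p, lp_p
                        acc_r[r_ix] = 1.0
                ad_ridge.record(acc_r)
            else:
                acc_s = False

            # --- log auxiliary (NB shape / Beta precision / noise sd)
            if fix_aux is None:
                prop_la = log_aux + ad_scalar.step[1] * rng.standard_normal()
                ll_pt_p = fam.loglik_pointwise(y, eta, prop_la)
                ll_p = float(np.sum(ll_pt_p))
                d_prior = float(
                    _normal_logpdf(prop_la, pc.aux_scale)
                    - _normal_logpdf(log_aux, pc.aux_scale)
                )
                acc_a = np.log(rng.uniform()) < ll_p - ll + d_prior
                if acc_a:
                    log_aux, ll_pt, ll = prop_la, ll_pt_p, ll_p
            else:
                acc_a = False
            ad_scalar.record(np.array([float(acc_s), float(acc_a)]))

            if it >= warmup:
                k = it - warmup
                out[c, k, :p] = T @ beta_s
                out[c, k, p] = log_aux
                if use_ri:
                    out[c, k, p + 1] = log_sigma
                    out[c, k, p + 2 :] = u

        accept_info[f"chain{c}_beta"] = ad_beta.rate()
        if use_ri:
            accept_info[f"chain{c}_u"] = ad_u.rate()
        accept_info[f"chain{c}_scalar"] = ad_scalar.rate()

    names = param_names(data, spec) if use_ri else (
        list(data.colnames) + [fam.aux_name]
    )
    return PosteriorDraws(
        draws=out,
        names=names,
        seed=int(seed),
        iterations=iterations,
        warmup=warmup,
        accept_rates=accept_info,
    )


# ---------------------------------------------------------------------------
# summaries


@dataclass
class FitSummary:
    """Per-parameter posterior summary with CI-based effect flags."""

    table: pd.DataFrame  # index: parameter names
    n_obs: int

    def effect(self, name: str) -> bool:
        return bool(self.table.loc[name, "effect"])

    def to_json_dict(self) -> dict:
        return {
            "n_obs": self.n_obs,
            "parameters": {
                name: {k: (bool(v) if k == "effect" else float(v))
                       for k, v in row.items()}
                for name, row in self.table.to_dict("index").items()
            },
        }


def summarize_fit(
    draws: PosteriorDraws, n_obs: int = 0, params: list[str] | None = None
) -> FitSummary:
    """Pooled posterior means, equal-tailed 95% CIs, convergence
    diagnostics, and the CI-excludes-zero effect flag."""
    from . import diagnostics as diag

    if draws.chains * draws.kept < 100:
        raise ValueError("need at least 100 pooled draws to summarize")
    rows = {}
    for name in params or draws.names:
        x = draws.get(name)
        pooled = x.reshape(-1)
        lo, hi = np.percentile(pooled, [2.5, 97.5])
        bulk, tail = diag.ess(x)
        rows[name] = {
            "mean": float(np.mean(pooled)),
            "q2.5": float(lo),
            "q97.5": float(hi),
            "rhat": float(diag.split_rhat(x)),
            "ess_bulk": float(bulk),
            "ess_tail": float(tail),
            "effect": not (lo <= 0.0 <= hi),
        }
    return FitSummary(table=pd.DataFrame.from_dict(rows, orient="index"),
                      n_obs=int(n_obs))


def pointwise_loglik(
    draws: PosteriorDraws, data: GLMMData, spec: ModelSpec, thin: int = 10
) -> np.ndarray:
    """(draws x observations) log-likelihood matrix for PSIS-LOO.

    Thinning keeps the matrix small; PSIS needs a few hundred draws.
    """
    fam = spec.make_family()
    flat = draws.draws.reshape(-1, draws.draws.shape[2])[::thin]
    p = data.p
    betas = flat[:, :p]
    log_aux = flat[:, p]
    eta = betas @ data.X.T
    if spec.include_random_intercept and data.n_groups:
        u = flat[:, p + 2 :]
        eta = eta + u[:, data.group]
    return fam.loglik_pointwise(data.y[None, :], eta, log_aux[:, None])
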