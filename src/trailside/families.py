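"""Response families for the hierarchical models.

Each family maps a linear predictor ``eta`` and an auxiliary parameter
(sampled on the log scale) to pointwise log-likelihoods and can simulate
replicated responses for posterior predictive checks.

* ``NegativeBinomial`` — mean ``mu = exp(eta)``, shape ``phi``, variance
  ``mu + mu^2/phi``; used for rounded height/diameter (cm).
* ``BetaFamily`` — mean ``mu = linkinv(eta)`` (logit by default, log
  selectable), precision ``phi``; shape parameters ``mu*phi`` and
  ``(1-mu)*phi``; used for relative reproduction and percent cover.
* ``NormalFamily`` — identity link with noise sd ``exp(log_aux)``; a
  validation family whose conjugate posteriors are known in closed form.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln

__all__ = ["Family", "NegativeBinomial", "BetaFamily", "NormalFamily", "get_family"]

_LOG_2PI = float(np.log(2.0 * np.pi))


class Family:
    name: str = ""
    aux_name: str = "log_aux"

    def loglik_pointwise(self, y, eta, log_aux):  # pragma: no cover - interface
        raise NotImplementedError

    def loglik(self, y, eta, log_aux) -> float:
        return float(np.sum(self.loglik_pointwise(y, eta, log_aux)))

    def simulate(self, rng, eta, log_aux):  # pragma: no cover - interface
        raise NotImplementedError

    def validate_response(self, y) -> None:
        raise NotImplementedError

    def default_init(self, y):
        """(intercept, log_aux) starting values informed by the data."""
        raise NotImplementedError


class NegativeBinomial(Family):
    name = "negative_binomial"
    aux_name = "log_shape"

    def loglik_pointwise(self, y, eta, log_aux):
        phi = np.exp(log_aux)
        mu = np.exp(eta)
        log_phi_mu = np.log(phi + mu)
        return (
            gammaln(y + phi)
            - gammaln(phi)
            - gammaln(y + 1.0)
            + phi * (log_aux - log_phi_mu)
            + y * (eta - log_phi_mu)
        )

    def simulate(self, rng, eta, log_aux):
        phi = np.exp(log_aux)
        mu = np.exp(eta)
        return rng.negative_binomial(phi, phi / (phi + mu))

    def validate_response(self, y) -> None:
        y = np.asarray(y)
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise ValueError(
                "negative binomial responses must be non-negative integers; "
                "apply round_for_nb to measured sizes first"
            )

    def default_init(self, y):
        return float(np.log(np.mean(y) + 0.5)), 0.0


class BetaFamily(Family):
    name = "beta"
    aux_name = "log_precision"

    def __init__(self, link: str = "logit"):
        if link not in ("logit", "log"):
            raise ValueError("beta mean link must be 'logit' or 'log'")
        self.link = link

    def mean(self, eta):
        if self.link == "logit":
            return expit(eta)
        return np.exp(eta)

    def loglik_pointwise(self, y, eta, log_aux):
        phi = np.exp(log_aux)
        mu = self.mean(eta)
        # under the log mean-link mu can leave (0,1): reject, don't raise
        if np.any(mu <= 0.0) or np.any(mu >= 1.0):
            return np.full(np.shape(y), -np.inf)
        a = mu * phi
        b = (1.0 - mu) * phi
        return (
            gammaln(phi)
            - gammaln(a)
            - gammaln(b)
            + (a - 1.0) * np.log(y)
            + (b - 1.0) * np.log1p(-y)
        )

    def simulate(self, rng, eta, log_aux):
        phi = np.exp(log_aux)
        mu = np.clip(self.mean(eta), 1e-12, 1.0 - 1e-12)
        return rng.beta(mu * phi, (1.0 - mu) * phi)

    def validate_response(self, y) -> None:
        y = np.asarray(y)
        if np.any(y <= 0.0) or np.any(y >= 1.0):
            raise ValueError(
                "beta responses must lie strictly inside (0, 1); "
                "apply adjust_unit_interval first"
            )

    def default_init(self, y):
        m = float(np.mean(y))
        eta0 = float(np.log(m / (1.0 - m))) if self.link == "logit" else float(np.log(m))
        return eta0, 0.0


class NormalFamily(Family):
    name = "normal"
    aux_name = "log_sd"

    def loglik_pointwise(self, y, eta, log_aux):
        sd = np.exp(log_aux)
        z = (y - eta) / sd
        return -0.5 * z * z - log_aux - 0.5 * _LOG_2PI

    def simulate(self, rng, eta, log_aux):
        return rng.normal(eta, np.exp(log_aux))

    def validate_response(self, y) -> None:
        if not np.all(np.isfinite(np.asarray(y, dtype=float))):
            raise ValueError("normal responses must be finite")

    def default_init(self, y):
        return float(np.mean(y)), float(np.log(np.std(y) + 1e-6))


def get_family(name: str, link: str = "logit") -> Family:
    if name in ("negative_binomial", "nb"):
        return NegativeBinomial()
    if name == "beta":
        return BetaFamily(link=link)
    if name == "normal":
        return NormalFamily()
    raise ValueError(f"unknown family: {name!r}")
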