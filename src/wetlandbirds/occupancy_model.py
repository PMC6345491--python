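"""Single-season site-occupancy likelihood with imperfect detection.

The model: each site-unit i (a point-count location in one year) has a
latent occupancy state z_i ~ Bernoulli(psi_i) with
logit(psi_i) = x_i . alpha; given z_i = 1, each replicate visit j yields
y_ij ~ Bernoulli(p_ij) with logit(p_ij) = w_ij . beta; given z_i = 0 all
visits are 0. The closure assumption holds within a winter season.

Marginalizing z gives the site likelihood

    L_i = psi_i * prod_j p_ij^y_ij (1 - p_ij)^(1 - y_ij)
          + (1 - psi_i) * 1[sum_j y_ij = 0],

which is what WAIC's pointwise terms use. All computation is in log space;
the two-term marginal uses logaddexp so extreme coefficients cannot
underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .io_data import DesignMatrices, DetectionTable

__all__ = [
    "Params", "inv_logit", "site_marginal_likelihood", "log_likelihood",
    "conditional_z_probability", "pointwise_log_likelihood",
    "site_log_marginals",
]


@dataclass
class Params:
    """Logit-scale coefficients: alpha for occupancy, beta for detection."""

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if not (np.isfinite(self.alpha).all() and np.isfinite(self.beta).all()):
            raise ValueError("coefficients must be finite")


def inv_logit(x):
    """Logistic link inverse, 1 / (1 + e^-x); saturates stably."""
    return expit(x)


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("detection history must contain only 0 and 1")
    return y


def site_marginal_likelihood(psi: float, p, y) -> float:
    """Integrated likelihood of one site-unit's detection history.

    ``y`` holds only the non-missing visits. Equals the brute-force sum
    over the latent state z in {0, 1}.
    """
    p = np.asarray(p, dtype=float)
    y = _check_binary(y)
    det = float(np.prod(np.where(y == 1, p, 1.0 - p)))
    absent = 0.0 if y.any() else 1.0
    return psi * det + (1.0 - psi) * absent


def conditional_z_probability(psi: float, p, y) -> float:
    """P(z = 1 | y): the Gibbs full conditional of the latent state."""
    p = np.asarray(p, dtype=float)
    y = _check_binary(y)
    if y.any():
        return 1.0
    miss = psi * float(np.prod(1.0 - p))
    return miss / (miss + (1.0 - psi))


def _log_bernoulli_sums(eta_w: np.ndarray, y_w: np.ndarray,
                        site_index: np.ndarray, n_sites: int):
    """Per-site sums of visit-level Bernoulli log-likelihood on the logit scale.

    log p = -log(1+e^-eta), log(1-p) = -log(1+e^eta); both via logaddexp.
    """
    terms = y_w * eta_w - np.logaddexp(0.0, eta_w)
    return np.bincount(site_index, weights=terms, minlength=n_sites)


def site_log_marginals(alpha: np.ndarray, beta: np.ndarray,
                       design: DesignMatrices) -> np.ndarray:
    """Vector of log integrated site likelihoods for one coefficient draw."""
    eta_x = design.X @ np.asarray(alpha, dtype=float)
    eta_w = design.W @ np.asarray(beta, dtype=float)
    n = design.n_sites
    log_psi = -np.logaddexp(0.0, -eta_x)
    log_1mpsi = -np.logaddexp(0.0, eta_x)
    log_det = _log_bernoulli_sums(eta_w, design.y_w, design.w_site_index, n)
    occupied = log_psi + log_det
    out = np.where(design.any_detection, occupied,
                   np.logaddexp(occupied, log_1mpsi))
    return out


def log_likelihood(params: Params, design: DesignMatrices,
                   det: DetectionTable | None = None) -> float:
    """Total log-likelihood: sum over site-units of the log marginal."""
    if params.alpha.shape[0] != design.X.shape[1]:
        raise ValueError(
            f"alpha has {params.alpha.shape[0]} coefficients but X has "
            f"{design.X.shape[1]} columns"
        )
    if params.beta.shape[0] != design.W.shape[1]:
        raise ValueError(
            f"beta has {params.beta.shape[0]} coefficients but W has "
            f"{design.W.shape[1]} columns"
        )
    if det is not None and det.n_sites != design.n_sites:
        raise ValueError("detection table and design disagree on site-units")
    return float(site_log_marginals(params.alpha, params.beta, design).sum())


def pointwise_log_likelihood(draws, design: DesignMatrices,
                             det: DetectionTable | None = None) -> np.ndarray:
    """(draws x site-units) matrix of log integrated site likelihoods.

    ``draws`` is a :class:`~wetlandbirds.mcmc_inference.PosteriorDraws`
    (or anything exposing ``alpha_draws``/``beta_draws`` arrays). These
    are the pointwise terms WAIC is built from: the latent state is
    integrated out, so each site-unit contributes one exchangeable term.
    """
    alpha_draws = np.atleast_2d(draws.alpha_draws)
    beta_draws = np.atleast_2d(draws.beta_draws)
    if alpha_draws.shape[0] == 0:
        raise ValueError("no posterior draws supplied")
    out = np.empty((alpha_draws.shape[0], design.n_sites))
    for s in range(alpha_draws.shape[0]):
        out[s] = site_log_marginals(alpha_draws[s], beta_draws[s], design)
    return out
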