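"""Count and latent distributions used by the model.

Numerically stable log-probabilities, moments and samplers for the
negative binomial (NB), zero-inflated negative binomial (ZINB) and
diagonal Gaussian distributions.

The NB uses the mean/inverse-dispersion parameterization standard in
single-cell models: ``NB(mu, theta)`` with ``var = mu + mu**2 / theta``.
In the classic (r, p) parameterization this is ``r = theta`` and success
probability ``p = theta / (theta + mu)`` for the zero count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln


@dataclass
class NBParams:
    """Negative binomial parameters.

    Parameters
    ----------
    mean : array-like
        Mean ``mu`` per observation; strictly positive.
    dispersion : array-like
        Inverse-dispersion ``theta``; strictly positive.
        ``var = mu + mu**2 / theta``, so small theta = strong overdispersion.
    """

    mean: np.ndarray
    dispersion: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        if np.any(self.mean <= 0) or np.any(self.dispersion <= 0):
            raise ValueError("NB mean and dispersion must be strictly positive")


@dataclass
class ZINBParams:
    """ZINB = mixture of a point mass at zero (rate pi) and an NB component."""

    nb: NBParams
    dropout_prob: np.ndarray

    def __post_init__(self):
        self.dropout_prob = np.asarray(self.dropout_prob, dtype=float)
        if np.any(self.dropout_prob < 0) or np.any(self.dropout_prob > 1):
            raise ValueError("dropout_prob must lie in [0, 1]")


@dataclass
class GaussianParams:
    """Diagonal Gaussian with per-dimension mean and stddev."""

    mean: np.ndarray
    stddev: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.stddev = np.asarray(self.stddev, dtype=float)
        if np.any(self.stddev <= 0):
            raise ValueError("stddev must be strictly positive elementwise")


def _check_counts(x) -> np.ndarray:
    x = np.asarray(x)
    if np.any(x < 0) or not np.all(np.equal(np.mod(x, 1), 0)):
        raise ValueError("counts must be non-negative integers")
    return x.astype(float)


def nb_log_prob(x, params: NBParams) -> np.ndarray:
    """Log pmf of the negative binomial at count(s) ``x``.

    ``log NB(x; mu, theta) = lgamma(x+theta) - lgamma(theta) - lgamma(x+1)
    + theta*log(theta/(theta+mu)) + x*log(mu/(theta+mu))``
    """
    x = _check_counts(x)
    mu, theta = params.mean, params.dispersion
    log_theta_mu = np.logaddexp(np.log(theta), np.log(mu))
    return (
        gammaln(x + theta)
        - gammaln(theta)
        - gammaln(x + 1)
        + theta * (np.log(theta) - log_theta_mu)
        + x * (np.log(mu) - log_theta_mu)
    )


def zinb_log_prob(x, params: ZINBParams) -> np.ndarray:
    """Log pmf of the zero-inflated negative binomial.

    At zero the two mixture branches are combined in log space
    (log-sum-exp); positive counts get ``log(1-pi) + log NB(x)``.
    """
    x = _check_counts(x)
    pi = params.dropout_prob
    nb_ll = nb_log_prob(x, params.nb)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_1m_pi = np.log1p(-pi)
    # zero branch: log(pi + (1-pi) * NB(0)), combined in log space
    zero_case = np.logaddexp(log_pi, log_1m_pi + nb_ll)
    nonzero_case = log_1m_pi + nb_ll
    return np.where(x == 0, zero_case, nonzero_case)


def gaussian_kl_to_standard(q: GaussianParams) -> float:
    """KL(q || N(0, I)) in nats for a diagonal Gaussian q.

    Closed form ``sum_d 0.5 * (mu_d^2 + sigma_d^2 - 1 - log sigma_d^2)``;
    non-negative, zero iff q is the standard normal.
    """
    var = q.stddev**2
    return float(np.sum(0.5 * (q.mean**2 + var - 1.0 - np.log(var))))


def sample_nb(params: NBParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw NB counts via the gamma-Poisson mixture."""
    lam = rng.gamma(shape=params.dispersion, scale=params.mean / params.dispersion, size=n)
    return rng.poisson(lam)


def sample_zinb(params: ZINBParams, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` ZINB counts; reproducible given the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = sample_nb(params.nb, n, rng)
    dropped = rng.random(n) < params.dropout_prob
    counts[dropped] = 0
    return counts


def zinb_mean(params: ZINBParams) -> np.ndarray:
    """Expected value ``(1 - pi) * mu`` of the ZINB."""
    return (1.0 - params.dropout_prob) * params.nb.mean
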