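"""Vectorized truncated-normal density and sampling helpers.

The double Metropolis--Hastings step evaluates truncated-normal log-densities
for every stick variable at every iteration, so these are thin vectorized
wrappers over ``scipy.special`` kept free of per-call distribution-object
overhead. Checked against ``scipy.stats.truncnorm`` in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri

__all__ = ["truncnorm_logpdf", "truncnorm_rvs"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _standardize(mu, sigma2, lower, upper):
    sigma = np.sqrt(sigma2)
    a = (lower - mu) / sigma
    b = (upper - mu) / sigma
    return sigma, a, b


def _log_mass(a, b):
    # log(Phi(b) - Phi(a)), stable when both tails are extreme.
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    # Work on the side where the mass is representable: Phi(b)-Phi(a) =
    # Phi(-a)-Phi(-b), pick the orientation with the smaller magnitude args.
    flip = a + b > 0
    a_, b_ = np.where(flip, -b, a), np.where(flip, -a, b)
    lb = log_ndtr(b_)
    la = log_ndtr(a_)
    with np.errstate(divide="ignore"):
        out = lb + np.log1p(-np.exp(np.minimum(la - lb, 0.0)))
    return out


def truncnorm_logpdf(x, mu, sigma2, lower, upper):
    """Log-density of N(mu, sigma2) truncated to (lower, upper) at ``x``.

    All arguments broadcast; ``upper`` may be ``np.inf``.
    """
    x = np.asarray(x, dtype=float)
    sigma, a, b = _standardize(np.asarray(mu, float), np.asarray(sigma2, float),
                               lower, upper)
    z = (x - mu) / sigma
    logpdf = -0.5 * z * z - _LOG_SQRT_2PI - np.log(sigma) - _log_mass(a, b)
    inside = (x >= lower) & (x <= upper)
    return np.where(inside, logpdf, -np.inf)


def truncnorm_rvs(mu, sigma2, lower, upper, rng, size=None):
    """Draw from N(mu, sigma2) truncated to (lower, upper) by inverse CDF."""
    mu = np.asarray(mu, dtype=float)
    sigma, a, b = _standardize(mu, np.asarray(sigma2, float), lower, upper)
    pa = ndtr(a)
    pb = ndtr(b)
    if size is None:
        size = np.broadcast(mu, sigma).shape or None
    u = rng.uniform(size=size)
    z = ndtri(pa + u * (pb - pa))
    x = mu + sigma * z
    # Inverse-CDF in double precision can land exactly on a finite bound.
    tiny = 1e-12 * np.maximum(1.0, np.abs(sigma))
    return np.clip(x, lower + tiny, upper - tiny if np.all(np.isfinite(upper)) else np.inf)
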