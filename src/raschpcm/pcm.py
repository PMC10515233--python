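"""Partial credit model primitives.

The partial credit model (PCM) gives the probability that a person with
latent location ``theta`` (logits) responds in category ``x`` of an item
with ordered step thresholds ``delta_1..delta_m``::

    P(X = x | theta) = exp( sum_{k<=x} (theta - delta_k) ) / D(theta)

with the empty sum for ``x = 0`` and ``D`` the normalising constant over
categories ``0..m``.  Everything in this module is a pure function of
``theta`` and threshold arrays; no data containers are involved.

The elementary symmetric functions ``gamma_r`` — the sums over all response
patterns with a given total score of the pattern's exponential terms — are
the normalisers of the conditional likelihood used for item estimation.
They are computed by item-by-item convolution in log space, which is safe
for arbitrarily large or small thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .exceptions import InvalidArgumentError

__all__ = [
    "category_probability",
    "category_moments",
    "expected_score",
    "item_information",
    "test_information",
    "cumulative_thresholds",
    "elementary_symmetric",
    "log_esf",
    "ESFTable",
]


def cumulative_thresholds(thresholds: np.ndarray) -> np.ndarray:
    """Cumulative step parameters ``beta_x = sum_{k<=x} delta_k``, ``beta_0 = 0``."""
    thresholds = np.asarray(thresholds, dtype=float)
    return np.concatenate([[0.0], np.cumsum(thresholds)])


def category_probability(theta, thresholds) -> np.ndarray:
    """PCM category probabilities for one item.

    Parameters
    ----------
    theta : float or array of float
        Person location(s) in logits.
    thresholds : sequence of float
        Ordered step parameters ``delta_1..delta_m`` (logits).  They need
        not be increasing (disordered thresholds are legal in the PCM).

    Returns
    -------
    ndarray
        If ``theta`` is scalar, a vector of length ``m + 1`` over
        categories ``0..m``; if ``theta`` has shape ``(n,)``, an
        ``(n, m + 1)`` matrix.  Rows sum to 1.
    """
    theta = np.asarray(theta, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if not np.all(np.isfinite(thresholds)) or not np.all(np.isfinite(theta)):
        raise InvalidArgumentError("theta and thresholds must be finite")
    beta = cumulative_thresholds(thresholds)  # (m+1,)
    x = np.arange(beta.size)
    # log numerator: x*theta - beta_x ; normalise with logsumexp for stability
    lognum = np.multiply.outer(theta, x) - beta
    logprob = lognum - logsumexp(lognum, axis=-1, keepdims=True)
    return np.exp(logprob)


def category_moments(theta, thresholds) -> tuple[np.ndarray, ...]:
    """Conditional mean, variance, third and fourth central moments of X.

    Returns ``(mean, var, mu3, mu4)``, each shaped like ``theta``.  The
    variance is the item information; ``mu3`` is its derivative in
    ``theta`` and ``mu4`` enters the model-based variance of the fit
    mean-squares.
    """
    p = category_probability(theta, thresholds)
    x = np.arange(p.shape[-1], dtype=float)
    mean = p @ x
    d = x - mean[..., None] if np.ndim(mean) else x - mean
    var = np.sum(p * d**2, axis=-1)
    mu3 = np.sum(p * d**3, axis=-1)
    mu4 = np.sum(p * d**4, axis=-1)
    return mean, var, mu3, mu4


def expected_score(theta, thresholds_by_item: Sequence[np.ndarray]) -> np.ndarray:
    """Expected raw sum score ``sum_i E[X_i | theta]`` over a set of items.

    Strictly increasing and continuous in ``theta``, running from 0 to
    ``sum_i m_i`` across the real line.
    """
    if len(thresholds_by_item) == 0:
        raise InvalidArgumentError("item subset must be non-empty")
    theta = np.asarray(theta, dtype=float)
    total = np.zeros_like(theta, dtype=float)
    for th in thresholds_by_item:
        mean, _, _, _ = category_moments(theta, th)
        total = total + mean
    return total


def item_information(theta, thresholds) -> np.ndarray:
    """Fisher information of one PCM item: ``Var(X | theta)``."""
    _, var, _, _ = category_moments(theta, thresholds)
    return var


def test_information(theta, thresholds_by_item: Sequence[np.ndarray]) -> np.ndarray:
    """Test information function: sum of item informations at ``theta``."""
    if len(thresholds_by_item) == 0:
        raise InvalidArgumentError("item subset must be non-empty")
    theta = np.asarray(theta, dtype=float)
    total = np.zeros_like(theta, dtype=float)
    for th in thresholds_by_item:
        total = total + item_information(theta, th)
    return total


@dataclass
class ESFTable:
    """Elementary symmetric functions of one item subset.

    ``log_gamma[r]`` is the log of ``gamma_r``, the sum over all response
    patterns with total score ``r`` of ``prod_i exp(-beta_{i, x_i})``.
    ``gamma_0 = 1`` always, and the table has ``1 + sum_i m_i`` entries.
    """

    log_gamma: np.ndarray
    item_index: tuple = field(default=())

    @property
    def gamma(self) -> np.ndarray:
        return np.exp(self.log_gamma)

    @property
    def max_score(self) -> int:
        return self.log_gamma.size - 1

    def __len__(self) -> int:
        return self.log_gamma.size


def log_esf(log_eps_by_item: Sequence[np.ndarray]) -> np.ndarray:
    """Log elementary symmetric functions by convolution in log space.

    ``log_eps_by_item[i]`` is the vector ``(-beta_{i,0}, ..., -beta_{i,m_i})``
    (so its first entry is 0).  Returns ``log_gamma`` of length
    ``1 + sum_i m_i``.
    """
    acc = np.zeros(1)
    for le in log_eps_by_item:
        le = np.asarray(le, dtype=float)
        new = np.full(acc.size + le.size - 1, -np.inf)
        # log-space convolution: new[r] = logsumexp over x of acc[r-x] + le[x]
        for x in range(le.size):
            seg = acc + le[x]
            new[x : x + acc.size] = np.logaddexp(new[x : x + acc.size], seg)
        acc = new
    return acc


def elementary_symmetric(
    thresholds_by_item: Sequence[np.ndarray], item_subset: Sequence[int] | None = None
) -> ESFTable:
    """ESF table for an item subset, from per-item step parameters.

    Parameters
    ----------
    thresholds_by_item : sequence of arrays
        Step parameters ``delta`` per item (full instrument).
    item_subset : sequence of int, optional
        Indices of the items to include; defaults to all.
    """
    if item_subset is None:
        item_subset = range(len(thresholds_by_item))
    item_subset = tuple(item_subset)
    if len(item_subset) == 0:
        raise InvalidArgumentError("item subset must be non-empty")
    log_eps = [-cumulative_thresholds(thresholds_by_item[i]) for i in item_subset]
    return ESFTable(log_gamma=log_esf(log_eps), item_index=item_subset)
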