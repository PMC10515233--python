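"""Person ability estimation for fitted partial credit models.

The default estimator is Warm's weighted likelihood estimate (WLE), which
maximises ``l(theta) + log I(theta) / 2`` and stays finite for extreme
(zero or perfect) raw scores — those persons must still appear in
targeting displays and coverage percentages.  Plain maximum likelihood is
available for comparison; its extreme-score estimates are ``±inf``.

Because the raw score over a fixed observed item set is sufficient for
``theta``, estimation is performed once per (observed-item subset, raw
score) group and broadcast to the persons in it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .data import ResponseMatrix
from .exceptions import InvalidArgumentError, UndefinedPersonError
from .model import ItemParameters
from .pcm import category_moments

__all__ = ["PersonEstimates", "estimate_persons", "solve_theta"]


@dataclass
class PersonEstimates:
    """Per-person latent locations (logits), SEs and bookkeeping flags."""

    theta: np.ndarray
    se: np.ndarray
    raw_score: np.ndarray
    extreme: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta": self.theta,
                "se": self.se,
                "raw_score": self.raw_score,
                "extreme": self.extreme,
                "method": self.method,
            }
        )


def _score_moments(theta: float, thresholds: list[np.ndarray]):
    """Sum over items of (mean, information, d information / d theta)."""
    e = i = di = 0.0
    for th in thresholds:
        mean, var, mu3, _ = category_moments(theta, th)
        e += float(mean)
        i += float(var)
        di += float(mu3)
    return e, i, di


def solve_theta(raw_score: float, thresholds: list[np.ndarray],
                method: str = "wle", bracket: float = 15.0) -> tuple[float, float]:
    """Solve the (weighted) likelihood equation for one raw score.

    Returns ``(theta, se)`` with ``se = 1 / sqrt(I(theta))``.  For the MLE
    the estimating equation is ``r - E[R | theta] = 0``; the WLE adds
    Warm's bias correction ``I'(theta) / (2 I(theta))``.
    """
    max_score = sum(th.size for th in thresholds)
    if method == "mle":
        if raw_score <= 0 or raw_score >= max_score:
            theta = -np.inf if raw_score <= 0 else np.inf
            return theta, np.inf

        def g(t):
            e, _, _ = _score_moments(t, thresholds)
            return raw_score - e

    elif method == "wle":

        def g(t):
            e, i, di = _score_moments(t, thresholds)
            return raw_score - e + di / (2.0 * i)

    else:
        raise InvalidArgumentError(f"unknown person estimation method {method!r}")

    lo, hi = -bracket, bracket
    while g(lo) < 0 and lo > -60:
        lo *= 2
    while g(hi) > 0 and hi < 60:
        hi *= 2
    theta = optimize.brentq(g, lo, hi, xtol=1e-10)
    _, info, _ = _score_moments(theta, thresholds)
    return theta, 1.0 / np.sqrt(info)


def estimate_persons(rm: ResponseMatrix, ip: ItemParameters,
                     method: str = "wle") -> PersonEstimates:
    """Estimate every person's location given fitted item parameters.

    Persons are grouped by observed item subset and raw score; extreme
    scores are flagged (and finite under WLE).  Raises
    :class:`UndefinedPersonError` if a person answered no items.
    """
    obs = ~rm.missing_mask
    if np.any(obs.sum(axis=1) == 0):
        p = int(np.flatnonzero(obs.sum(axis=1) == 0)[0])
        raise UndefinedPersonError(f"person {p} has no observed responses")

    th_all = [ip.thresholds[ip.item_ids.index(i)] for i in rm.item_ids]
    raw = np.where(rm.missing_mask, 0, rm.data).sum(axis=1)
    maxraw = np.array([sum(th_all[j].size for j in np.flatnonzero(obs[p]))
                       for p in range(rm.n_persons)])
    extreme = (raw == 0) | (raw == maxraw)

    theta = np.empty(rm.n_persons)
    se = np.empty(rm.n_persons)
    cache: dict[tuple, tuple[float, float]] = {}
    for p in range(rm.n_persons):
        key = (obs[p].tobytes(), int(raw[p]))
        if key not in cache:
            ths = [th_all[j] for j in np.flatnonzero(obs[p])]
            cache[key] = solve_theta(raw[p], ths, method=method)
        theta[p], se[p] = cache[key]

    return PersonEstimates(theta=theta, se=se, raw_score=raw.astype(int),
                           extreme=extreme, method=method)
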