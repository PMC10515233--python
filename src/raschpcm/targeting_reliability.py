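"""Targeting, response-category ordering, test information and conditional PSI.

Reliability is reported conditionally rather than as a point estimate:
the test information function ``TI(theta)`` (sum of item informations)
maps to a person separation index through

    PSI(theta) = 1 - 1 / TI(theta)        (clipped at 0 when TI < 1)

so TI = 3.33 corresponds to PSI 0.7 and TI = 5.0 to PSI 0.8.  The profile
reports the theta interval(s) where PSI clears a threshold and the share
of the sample located inside, above and below — the information-based
alternative to a sample-level reliability coefficient.

Targeting compares the person distribution with the distribution of item
step thresholds on the shared logit scale (Wright-map style); the step
parameters themselves are used as the threshold locations (Thurstonian
thresholds can be substituted by the caller if preferred).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import InvalidArgumentError
from .model import ItemParameters
from .pcm import test_information
from .persons import PersonEstimates

__all__ = [
    "ReliabilityProfile",
    "TargetingSummary",
    "psi_from_information",
    "information_for_psi",
    "ordered_thresholds_check",
    "targeting_summary",
    "reliability_profile",
]

THETA_GRID = (-6.0, 6.0, 0.01)


def psi_from_information(ti):
    """Conditional person separation index from test information."""
    ti = np.asarray(ti, dtype=float)
    return np.clip(1.0 - 1.0 / np.maximum(ti, 1e-300), 0.0, None)


def information_for_psi(psi: float) -> float:
    """Invert the PSI-information relation (e.g. PSI 0.7 -> TI 10/3)."""
    if not 0 < psi < 1:
        raise InvalidArgumentError("psi must be in (0, 1)")
    return float(optimize.brentq(lambda t: psi_from_information(t) - psi,
                                 1.0 + 1e-12, 1e12))


def ordered_thresholds_check(ip: ItemParameters) -> pd.DataFrame:
    """Flag items whose step thresholds are not increasing with category.

    Disordered thresholds signal response-category malfunction.  Reports
    the first offending adjacent pair and the gap per flagged item.
    """
    rows = []
    for iid, th in zip(ip.item_ids, ip.thresholds):
        gaps = np.diff(th)
        bad = np.flatnonzero(gaps < 0)
        rows.append(
            {
                "item": iid,
                "disordered": bad.size > 0,
                "first_bad_pair": f"({bad[0] + 1},{bad[0] + 2})" if bad.size else "",
                "gap": float(gaps[bad[0]]) if bad.size else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("item")


@dataclass
class TargetingSummary:
    """Person and item-threshold distributions on the common logit scale."""

    person_mean: float
    person_sd: float
    item_location_mean: float
    item_location_sd: float
    thresholds: np.ndarray          # all step thresholds pooled
    person_hist: tuple[np.ndarray, np.ndarray]
    threshold_hist: tuple[np.ndarray, np.ndarray]
    warnings: list[str]


def targeting_summary(pe: PersonEstimates, ip: ItemParameters,
                      bins: int = 40) -> TargetingSummary:
    """Means/SDs of person and item distributions plus Wright-map histograms."""
    theta = pe.theta[np.isfinite(pe.theta)]
    warn = []
    if theta.size < 2:
        warn.append("fewer than 2 located persons: SD undefined")
        sd = np.nan
    else:
        sd = float(np.std(theta, ddof=1))
    locs = ip.item_locations
    pooled = np.concatenate(ip.thresholds)
    lo = min(theta.min(initial=0.0), pooled.min()) - 0.5
    hi = max(theta.max(initial=0.0), pooled.max()) + 0.5
    edges = np.linspace(lo, hi, bins + 1)
    return TargetingSummary(
        person_mean=float(np.mean(theta)) if theta.size else np.nan,
        person_sd=sd,
        item_location_mean=float(np.mean(locs)),
        item_location_sd=float(np.std(locs, ddof=1)) if locs.size > 1 else np.nan,
        thresholds=pooled,
        person_hist=(np.histogram(theta, bins=edges)[0], edges),
        threshold_hist=(np.histogram(pooled, bins=edges)[0], edges),
        warnings=warn,
    )


@dataclass
class ReliabilityProfile:
    """TIF and conditional PSI over a theta grid, with coverage percentages."""

    grid: np.ndarray
    tif: np.ndarray
    psi: np.ndarray
    psi_threshold: float
    intervals: list[tuple[float, float]]   # theta ranges with PSI >= threshold
    pct_inside: float
    pct_above: float
    pct_below: float
    pct_above_max_threshold: float
    pct_below_min_threshold: float
    max_threshold: float
    min_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"theta": self.grid, "tif": self.tif, "psi": self.psi})


def _crossing(grid, psi, level, i, rising):
    """Linear interpolation of the grid crossing between i and i+1."""
    x0, x1 = grid[i], grid[i + 1]
    y0, y1 = psi[i], psi[i + 1]
    if y1 == y0:
        return x1 if rising else x0
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def reliability_profile(ip: ItemParameters, pe: PersonEstimates,
                        psi_threshold: float = 0.7,
                        grid: tuple[float, float, float] = THETA_GRID,
                        ) -> ReliabilityProfile:
    """Conditional reliability profile and person-coverage percentages.

    The grid is widened if any person estimate falls outside it, so the
    coverage partition always accounts for the whole sample (extreme
    persons enter through their finite WLE locations).
    """
    theta_p = pe.theta[np.isfinite(pe.theta)]
    lo, hi, step = grid
    if theta_p.size:
        lo = min(lo, float(theta_p.min()) - 1.0)
        hi = max(hi, float(theta_p.max()) + 1.0)
    g = np.arange(lo, hi + step / 2, step)
    tif = test_information(g, ip.thresholds)
    psi = psi_from_information(tif)

    above = psi >= psi_threshold
    intervals = []
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j + 1 < above.size and above[j + 1]:
                j += 1
            left = g[i] if i == 0 else _crossing(g, psi, psi_threshold, i - 1, True)
            right = g[j] if j == above.size - 1 else _crossing(
                g, psi, psi_threshold, j, False)
            intervals.append((float(left), float(right)))
            i = j + 1
        else:
            i += 1

    n = theta_p.size
    if n and intervals:
        inside = np.zeros(n, dtype=bool)
        for a, b in intervals:
            inside |= (theta_p >= a) & (theta_p <= b)
        hi_end = max(b for _, b in intervals)
        lo_end = min(a for a, _ in intervals)
        pct_inside = 100.0 * inside.mean()
        pct_above = 100.0 * float(np.mean(theta_p > hi_end))
        pct_below = 100.0 * float(np.mean(theta_p < lo_end))
    else:
        pct_inside, pct_above, pct_below = 0.0, 0.0, 100.0 if n else 0.0

    pooled = np.concatenate(ip.thresholds)
    tmax, tmin = float(pooled.max()), float(pooled.min())
    return ReliabilityProfile(
        grid=g, tif=tif, psi=psi, psi_threshold=psi_threshold,
        intervals=intervals,
        pct_inside=pct_inside, pct_above=pct_above, pct_below=pct_below,
        pct_above_max_threshold=100.0 * float(np.mean(theta_p > tmax)) if n else 0.0,
        pct_below_min_threshold=100.0 * float(np.mean(theta_p < tmin)) if n else 0.0,
        max_threshold=tmax, min_threshold=tmin,
    )
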