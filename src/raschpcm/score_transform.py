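"""Ordinal sum score to interval (logit) score conversion tables.

For a fixed, completely answered item subset the raw sum score is the
sufficient statistic for the person location, so each raw score maps to
one logit measure: the table row for an interior score ``r`` solves
``E[R | theta] = r`` (which coincides with maximum likelihood scoring),
and the extreme scores 0 and maximum — where the MLE is infinite — are
located by the weighted likelihood estimate so the table stays finite.
``SE = 1 / sqrt(TI(theta))`` throughout.  The table is only valid for
persons who answered every item of the subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import InvalidArgumentError
from .model import ItemParameters
from .pcm import expected_score, test_information
from .persons import solve_theta

__all__ = ["ScoreConversionTable", "score_to_theta_table", "apply_table"]


@dataclass
class ScoreConversionTable:
    """Raw score -> (logit measure, SE) lookup for a named item subset."""

    table: pd.DataFrame     # index raw_score; columns theta, se
    item_ids: list[str]
    extreme_handling: str = "WLE"

    @property
    def max_score(self) -> int:
        return int(self.table.index.max())

    def to_csv(self, path):
        self.table.to_csv(path)


def score_to_theta_table(ip: ItemParameters, item_subset) -> ScoreConversionTable:
    """Build the conversion table for ``item_subset`` from fitted thresholds."""
    missing = [i for i in item_subset if i not in ip.item_ids]
    if missing:
        raise InvalidArgumentError(f"items not in the fitted parameters: {missing}")
    if not list(item_subset):
        raise InvalidArgumentError("item subset must be non-empty")
    ths = [ip.thresholds[ip.item_ids.index(i)] for i in item_subset]
    max_score = int(sum(t.size for t in ths))

    rows = []
    for r in range(max_score + 1):
        if r == 0 or r == max_score:
            theta, se = solve_theta(r, ths, method="wle")
        else:
            theta = float(optimize.brentq(
                lambda t: float(expected_score(t, ths)) - r, -60, 60, xtol=1e-10))
            se = 1.0 / np.sqrt(float(test_information(theta, ths)))
        rows.append({"raw_score": r, "theta": theta, "se": se})
    table = pd.DataFrame(rows).set_index("raw_score")
    if not np.all(np.diff(table["theta"]) > 0):
        raise AssertionError("conversion table is not strictly increasing")
    return ScoreConversionTable(table=table, item_ids=list(item_subset))


def apply_table(tbl: ScoreConversionTable, raw_scores) -> pd.DataFrame:
    """Vectorised lookup of interval scores and SEs for integer raw scores."""
    raw = np.asarray(raw_scores)
    if raw.size and (not np.issubdtype(raw.dtype, np.integer)
                     and np.any(raw != np.round(raw))):
        raise InvalidArgumentError("raw scores must be integers")
    raw = raw.astype(int)
    bad = (raw < 0) | (raw > tbl.max_score)
    if np.any(bad):
        p = int(np.flatnonzero(bad)[0])
        raise InvalidArgumentError(
            f"raw score {raw[p]} out of range 0..{tbl.max_score} (person {p})"
        )
    out = tbl.table.loc[raw].reset_index()
    out.index = pd.RangeIndex(raw.size)
    return out
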