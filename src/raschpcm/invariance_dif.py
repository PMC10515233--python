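"""Differential item functioning (DIF) by group comparison of item locations.

The model is fitted separately within each group by conditional maximum
likelihood; the two metrics are then equated by forcing the mean location
of an *anchor* item set to agree across groups, and DIF size per item is
the absolute anchored location difference in logits.  The conventional
screening cutoff is 0.5 logits.  The anchor defaults to all items and is
iteratively purified: items flagged at the cutoff are removed from the
anchor (at most a few rounds) so biased items do not contaminate the
common metric.

A global invariance test compares the joint conditional likelihood with
the sum of the group-specific ones by a likelihood-ratio chi-square.  For
an ordered covariate, ``dif_split_search`` scans all admissible cut
points with this statistic and Bonferroni-adjusts the minimum p-value —
a one-level approximation to model-based recursive partitioning, which
is adequate when a single split per covariate is of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ResponseMatrix
from .exceptions import DataError, InvalidArgumentError
from .model import ItemParameters, PartialCreditModel

__all__ = ["DIFReport", "dif_two_group", "dif_split_search", "age_preset_groups"]

DIF_CUTOFF = 0.5
MIN_GROUP_WARN = 50
MAX_PURIFY = 3


@dataclass
class DIFReport:
    """Anchored per-item location comparison between two groups."""

    covariate: str
    split: str
    table: pd.DataFrame        # location_a, location_b, dif_size, easier_in, flag
    anchor_items: list[str]
    p_value: float             # global LR invariance test
    lr_stat: float
    df: int
    group_sizes: tuple[int, int]
    warnings: list[str]

    @property
    def flagged_items(self) -> list[str]:
        return list(self.table.index[self.table["flag"]])


def _group_matrix(rm: ResponseMatrix, sel: np.ndarray) -> ResponseMatrix:
    return ResponseMatrix(
        data=rm.data[sel], missing_mask=rm.missing_mask[sel],
        item_meta=rm.item_meta, person_meta=rm.person_meta.iloc[sel],
    )


def _fit_group(rm: ResponseMatrix, label: str):
    try:
        return PartialCreditModel(rm).fit(compute_se=False)
    except DataError as err:
        raise DataError(f"group {label!r}: {err}") from err


def dif_two_group(rm: ResponseMatrix, groups, covariate: str = "group",
                  split: str = "", cutoff: float = DIF_CUTOFF,
                  max_purify: int = MAX_PURIFY) -> DIFReport:
    """DIF analysis between the two groups given by boolean ``groups``.

    ``groups`` is a boolean array (True = group B) partitioning the
    sample.  Returns anchored locations per group, DIF sizes, the easier
    group per item and the global likelihood-ratio test.
    """
    groups = np.asarray(groups, dtype=bool)
    if groups.shape[0] != rm.n_persons:
        raise InvalidArgumentError("groups must have one entry per person")
    warn = []
    n_a, n_b = int((~groups).sum()), int(groups.sum())
    if min(n_a, n_b) < 2:
        raise InvalidArgumentError("both groups need at least 2 persons")
    if min(n_a, n_b) < MIN_GROUP_WARN:
        warn.append(f"small group (n = {min(n_a, n_b)}): estimates are unstable")

    rm_a, rm_b = _group_matrix(rm, ~groups), _group_matrix(rm, groups)
    res_a = _fit_group(rm_a, "A")
    res_b = _fit_group(rm_b, "B")
    res_joint = _fit_group(rm, "joint")

    loc_a = pd.Series(res_a.params.item_locations, index=res_a.params.item_ids)
    loc_b = pd.Series(res_b.params.item_locations, index=res_b.params.item_ids)

    anchor = list(loc_a.index)
    for _ in range(max_purify + 1):
        shift = (loc_a[anchor] - loc_b[anchor]).mean()
        diff = (loc_a - loc_b) - shift
        flagged = set(diff.index[np.abs(diff) >= cutoff])
        new_anchor = [i for i in loc_a.index if i not in flagged]
        if new_anchor == anchor or not new_anchor:
            break
        anchor = new_anchor

    dif_size = np.abs(diff)
    easier = np.where(diff > 0, "B", np.where(diff < 0, "A", "-"))
    table = pd.DataFrame(
        {
            "location_a": loc_a,
            "location_b": loc_b + shift,
            "dif_size": dif_size,
            "easier_in": easier,  # group with the lower anchored location
            "flag": dif_size >= cutoff,
        }
    )

    lr = 2.0 * (res_a.loglike + res_b.loglike - res_joint.loglike)
    df = res_joint.df_model()
    p = float(stats.chi2.sf(max(lr, 0.0), df))
    return DIFReport(
        covariate=covariate, split=split, table=table, anchor_items=anchor,
        p_value=p, lr_stat=float(lr), df=df, group_sizes=(n_a, n_b),
        warnings=warn,
    )


def dif_split_search(rm: ResponseMatrix, covariate: str,
                     min_group: int = MIN_GROUP_WARN, alpha: float = 0.05,
                     cutoff: float = DIF_CUTOFF):
    """Exhaustive single-split DIF search over an ordered covariate.

    Candidate cuts are all observed values leaving at least ``min_group``
    persons on each side; each is scored by the likelihood-ratio
    invariance statistic and the winning cut's p-value is Bonferroni
    adjusted for the number of candidates.  Returns ``(best_cut, report)``
    or ``(None, None)`` when no admissible or significant split exists.
    """
    if covariate not in rm.person_meta.columns:
        raise InvalidArgumentError(f"covariate {covariate!r} not in person_meta")
    values = pd.to_numeric(rm.person_meta[covariate], errors="coerce").to_numpy()
    if np.isnan(values).any():
        raise DataError(f"covariate {covariate!r} has missing/non-numeric values")
    uniq = np.unique(values)
    if uniq.size < 3:
        if uniq.size < 2:
            return None, None
        # a binary covariate has exactly one candidate cut
        uniq = np.array([uniq[0], uniq[0], uniq[1]])

    candidates = [c for c in uniq[:-1]
                  if (values <= c).sum() >= min_group
                  and (values > c).sum() >= min_group]
    candidates = sorted(set(candidates))
    if not candidates:
        return None, None

    best = None
    for c in candidates:
        rep = dif_two_group(rm, values > c, covariate=covariate,
                            split=f"{covariate} <= {c} vs > {c}", cutoff=cutoff)
        if best is None or rep.lr_stat > best[1].lr_stat:
            best = (c, rep)

    cut, rep = best
    p_adj = min(1.0, rep.p_value * len(candidates))
    rep.p_value = p_adj
    rep.warnings.append(f"p-value Bonferroni-adjusted over {len(candidates)} cuts")
    if p_adj > alpha:
        return None, rep
    return cut, rep


def age_preset_groups(rm: ResponseMatrix, cut: int = 31) -> np.ndarray:
    """Named age dichotomisations (cut at 31 or 20 years): True = older group."""
    if "age" not in rm.person_meta.columns:
        raise InvalidArgumentError("person_meta lacks an 'age' column")
    return pd.to_numeric(rm.person_meta["age"]).to_numpy() > cut
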