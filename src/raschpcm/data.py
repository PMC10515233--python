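"""Response-matrix container, item metadata and instrument presets.

The package is preconfigured for the Perceived Stress Scale (PSS): 14
five-category Likert items (codes 0..4), of which items 4, 5, 6, 7, 9, 10
and 13 are positively worded.  The short-form memberships (PSS-10, PSS-4)
follow the standard published versions of the instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, InvalidArgumentError

__all__ = [
    "ResponseMatrix",
    "read_responses",
    "pss_item_meta",
    "ITEM_SUBSETS",
    "POSITIVE_ITEMS",
]

# Standard PSS item subsets, by item id.  The negative7/positive7 split is
# by item wording; negative6_pss10 is the negative subscale of the PSS-10.
POSITIVE_ITEMS = ("q4", "q5", "q6", "q7", "q9", "q10", "q13")
ITEM_SUBSETS: dict[str, tuple[str, ...]] = {
    "PSS14": tuple(f"q{i}" for i in range(1, 15)),
    "PSS10": ("q1", "q2", "q3", "q6", "q7", "q8", "q9", "q10", "q11", "q14"),
    "PSS4": ("q2", "q6", "q7", "q14"),
    "negative7": ("q1", "q2", "q3", "q8", "q11", "q12", "q14"),
    "positive7": POSITIVE_ITEMS,
    "negative6_pss10": ("q1", "q2", "q3", "q8", "q11", "q14"),
}


def pss_item_meta() -> pd.DataFrame:
    """Item metadata table for the 14-item PSS (polarity, max category, versions)."""
    rows = []
    for iid in ITEM_SUBSETS["PSS14"]:
        versions = [v for v in ("PSS14", "PSS10", "PSS4") if iid in ITEM_SUBSETS[v]]
        rows.append(
            {
                "id": iid,
                "polarity": "positive" if iid in POSITIVE_ITEMS else "negative",
                "max_category": 4,
                "versions": ",".join(versions),
            }
        )
    return pd.DataFrame(rows).set_index("id")


@dataclass
class ResponseMatrix:
    """Persons x items integer responses with a missing mask and metadata.

    ``data`` holds integer category codes ``0..m_i`` (entries under the
    mask are arbitrary); ``missing_mask`` is True where no response was
    observed.  ``item_meta`` is indexed by item id with columns
    ``polarity``, ``max_category`` and optionally ``versions``;
    ``person_meta`` carries grouping covariates (gender, age, ...).
    """

    data: np.ndarray
    missing_mask: np.ndarray
    item_meta: pd.DataFrame
    person_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise DataError("response data must be 2-dimensional (persons x items)")
        n, k = self.data.shape
        if n < 2 or k < 2:
            raise DataError("need at least 2 persons and 2 items")
        if self.missing_mask is None:
            self.missing_mask = np.zeros((n, k), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.data.shape:
            raise DataError("missing_mask shape mismatch")
        if not np.issubdtype(self.data.dtype, np.integer):
            filled = np.where(self.missing_mask, 0, self.data)
            if not np.all(np.isfinite(filled)) or np.any(filled != np.round(filled)):
                raise DataError("observed responses must be integers")
            self.data = np.where(self.missing_mask, 0, filled).astype(int)
        if len(self.item_meta) != k:
            raise DataError(
                f"item_meta has {len(self.item_meta)} rows for {k} items"
            )
        if self.person_meta is None:
            self.person_meta = pd.DataFrame(index=pd.RangeIndex(n))
        self._validate_codes()

    def _validate_codes(self):
        obs = ~self.missing_mask
        for j, iid in enumerate(self.item_ids):
            m = int(self.item_meta["max_category"].iloc[j])
            col = self.data[:, j][obs[:, j]]
            bad = (col < 0) | (col > m)
            if np.any(bad):
                row = int(np.flatnonzero(obs[:, j])[np.argmax(bad)])
                raise DataError(
                    f"response {col[bad][0]} out of range 0..{m} "
                    f"(item {iid!r}, person row {row})"
                )

    # -- basic views -------------------------------------------------
    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]

    @property
    def item_ids(self) -> list[str]:
        return list(self.item_meta.index)

    @property
    def max_categories(self) -> np.ndarray:
        return self.item_meta["max_category"].to_numpy(dtype=int)

    def observed_counts(self) -> pd.DataFrame:
        """Category frequency table (items x categories 0..max)."""
        mmax = int(self.max_categories.max())
        out = np.zeros((self.n_items, mmax + 1), dtype=int)
        obs = ~self.missing_mask
        for j in range(self.n_items):
            col = self.data[:, j][obs[:, j]]
            out[j] = np.bincount(col, minlength=mmax + 1)
        return pd.DataFrame(out, index=self.item_ids, columns=range(mmax + 1))

    def raw_scores(self) -> np.ndarray:
        """Sum of observed responses per person."""
        return np.where(self.missing_mask, 0, self.data).sum(axis=1)

    def thin_items(self) -> list[str]:
        """Items with fewer than 2 observed distinct categories (flagged, not dropped)."""
        counts = self.observed_counts()
        return [iid for iid in self.item_ids if (counts.loc[iid] > 0).sum() < 2]

    # -- transformations ---------------------------------------------
    def subset(self, item_ids) -> "ResponseMatrix":
        """Restrict to an item subset, by ids or a named preset (e.g. 'negative7')."""
        if isinstance(item_ids, str):
            try:
                item_ids = ITEM_SUBSETS[item_ids]
            except KeyError:
                raise InvalidArgumentError(
                    f"unknown preset {item_ids!r}; options: {sorted(ITEM_SUBSETS)}"
                ) from None
        idx = [self.item_ids.index(i) for i in item_ids]
        return ResponseMatrix(
            data=self.data[:, idx].copy(),
            missing_mask=self.missing_mask[:, idx].copy(),
            item_meta=self.item_meta.iloc[idx].copy(),
            person_meta=self.person_meta.copy(),
        )

    def reverse_code(self, item_ids=None) -> "ResponseMatrix":
        """Reverse-code items (x -> m - x); default: all positively worded items.

        Full-scale analyses reverse the positively worded items so every
        item points in the distress direction; subscale analyses keep the
        raw orientation.
        """
        if item_ids is None:
            item_ids = [
                iid
                for iid, pol in self.item_meta["polarity"].items()
                if pol == "positive"
            ]
        data = self.data.copy()
        for iid in item_ids:
            j = self.item_ids.index(iid)
            m = int(self.item_meta["max_category"].iloc[j])
            data[:, j] = np.where(self.missing_mask[:, j], data[:, j], m - data[:, j])
        return ResponseMatrix(
            data=data,
            missing_mask=self.missing_mask.copy(),
            item_meta=self.item_meta.copy(),
            person_meta=self.person_meta.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Responses as a DataFrame with NA for missing entries."""
        df = pd.DataFrame(self.data, columns=self.item_ids).astype("Int64")
        return df.mask(pd.DataFrame(self.missing_mask, columns=self.item_ids))

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, item_meta: pd.DataFrame | None = None,
        person_meta: pd.DataFrame | None = None,
    ) -> "ResponseMatrix":
        """Build from a persons x items DataFrame (NaN/NA = missing)."""
        vals = df.to_numpy(dtype=float, na_value=np.nan)
        mask = ~np.isfinite(vals)
        data = np.where(mask, 0, vals)
        if item_meta is None:
            maxcat = np.nanmax(np.where(mask, np.nan, vals), axis=0)
            item_meta = pd.DataFrame(
                {
                    "polarity": "negative",
                    "max_category": np.maximum(1, maxcat).astype(int),
                },
                index=pd.Index(df.columns, name="id"),
            )
        if person_meta is None and df.index.name is not None:
            person_meta = pd.DataFrame(index=df.index)
        return cls(data=data, missing_mask=mask, item_meta=item_meta,
                   person_meta=person_meta)


def read_responses(path, meta_path=None) -> ResponseMatrix:
    """Read a response CSV (one row per person, integer cells, empty = missing).

    Covariate columns (non-item) are moved to ``person_meta``; item columns
    are those present in the metadata table, or every column whose values
    are all small non-negative integers if no metadata is given.  Category
    coding is 0-based.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise DataError(f"empty input file: {path}")
    if meta_path is not None:
        meta = pd.read_csv(meta_path).set_index("id")
    else:
        meta = None

    if meta is not None:
        item_cols = [c for c in df.columns if c in meta.index]
        if not item_cols:
            raise DataError("no metadata item ids found among CSV columns")
        meta = meta.loc[item_cols]
    else:
        item_cols = [c for c in df.columns if c.lower() not in ("gender", "age", "id")]
    cov_cols = [c for c in df.columns if c not in item_cols]

    sub = df[item_cols]
    for c in item_cols:
        col = pd.to_numeric(sub[c], errors="coerce")
        bad = col.isna() & sub[c].notna()
        if bad.any():
            r = int(np.flatnonzero(bad)[0])
            raise DataError(f"non-integer cell at row {r}, column {c!r}: {sub[c].iloc[r]!r}")
        sub = sub.assign(**{c: col})
    person_meta = df[cov_cols] if cov_cols else None
    return ResponseMatrix.from_dataframe(sub, item_meta=meta, person_meta=person_meta)
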