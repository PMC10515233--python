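"""Dimensionality screening of Rasch residuals.

Two complementary checks, both on the standardized residuals left after
removing the fitted Rasch dimension:

* principal component analysis of the item x item residual correlation
  matrix — a first eigenvalue of 2.0 or more signals a secondary
  dimension, and the first-contrast loadings show which items form it;
* pairwise residual correlations (Yen's Q3 on standardized residuals)
  screened against a *relative* cutoff: the mean of all item-pair
  residual correlations plus 0.2.  Pairs above it violate local
  independence.

Correlations use pairwise-complete observations so missing responses and
excluded extreme persons are handled without dropping whole rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .item_fit import ResidualMatrix

__all__ = [
    "DimensionalityReport",
    "residual_pca",
    "residual_correlations",
    "flag_dependent_pairs",
    "assess_unidimensionality",
    "dimensionality_report",
]

EIGENVALUE_CUTOFF = 2.0
RELATIVE_MARGIN = 0.2


@dataclass
class DimensionalityReport:
    """Evidence bundle: eigenvalues, first contrast, Q3 flags, verdict inputs."""

    eigenvalues: np.ndarray            # descending
    loadings: pd.Series                # first-contrast loading per item
    residual_corr: pd.DataFrame        # item x item, estimator: Q3
    mean_offdiag: float
    cutoff: float
    flagged_pairs: list[tuple[str, str, float]]
    estimator: str = "Q3 (pairwise-complete Pearson on standardized residuals)"

    @property
    def first_eigenvalue(self) -> float:
        return float(self.eigenvalues[0])


def _pairwise_corr(res: ResidualMatrix) -> pd.DataFrame:
    z = pd.DataFrame(res.z, columns=res.item_ids)
    return z.corr(min_periods=3)


def residual_pca(res: ResidualMatrix) -> tuple[np.ndarray, pd.Series]:
    """Eigenvalues and first-contrast loadings of the residual correlation matrix.

    Eigenvalues are those of the item x item correlation matrix of
    standardized residuals (they sum to the item count); loadings are the
    first eigenvector scaled by the square root of its eigenvalue, so
    their signs separate the item clusters of a secondary dimension.
    """
    corr = _pairwise_corr(res)
    n_persons = int(res.defined.any(axis=1).sum())
    if n_persons < len(res.item_ids):
        import warnings

        warnings.warn("fewer persons than items: residual PCA is rank-deficient",
                      stacklevel=2)
    vals, vecs = np.linalg.eigh(corr.to_numpy())
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    first = vecs[:, 0] * np.sqrt(max(vals[0], 0.0))
    # orient the first contrast so its largest-magnitude loading is positive
    if first[np.argmax(np.abs(first))] < 0:
        first = -first
    return vals, pd.Series(first, index=corr.index, name="first_contrast")


def flag_dependent_pairs(corr: pd.DataFrame,
                         margin: float = RELATIVE_MARGIN):
    """Apply the relative cutoff rule to a residual correlation matrix.

    The cutoff is ``mean(all off-diagonal pairs) + margin``; every pair
    strictly above it is flagged.  Returns ``(mean, cutoff, flagged)``
    with flagged as ``(item_a, item_b, r)`` triples.
    """
    a = corr.to_numpy(dtype=float)
    iu = np.triu_indices_from(a, k=1)
    pair_r = a[iu]
    mean_off = float(np.nanmean(pair_r))
    cutoff = mean_off + margin
    flagged = [
        (corr.index[i], corr.columns[j], float(a[i, j]))
        for i, j in zip(*iu)
        if np.isfinite(a[i, j]) and a[i, j] > cutoff
    ]
    return mean_off, cutoff, flagged


def residual_correlations(res: ResidualMatrix, margin: float = RELATIVE_MARGIN):
    """Q3 residual correlation matrix with relative-cutoff flags."""
    corr = _pairwise_corr(res)
    mean_off, cutoff, flagged = flag_dependent_pairs(corr, margin=margin)
    return corr, mean_off, cutoff, flagged


def dimensionality_report(res: ResidualMatrix,
                          margin: float = RELATIVE_MARGIN) -> DimensionalityReport:
    vals, loadings = residual_pca(res)
    corr, mean_off, cutoff, flagged = residual_correlations(res, margin=margin)
    return DimensionalityReport(
        eigenvalues=vals, loadings=loadings, residual_corr=corr,
        mean_offdiag=mean_off, cutoff=cutoff, flagged_pairs=flagged,
    )


def assess_unidimensionality(report: DimensionalityReport,
                             eigen_cutoff: float = EIGENVALUE_CUTOFF):
    """Verdict and rationale from a dimensionality report.

    Multidimensional iff the first eigenvalue reaches the cutoff or any
    residual-correlation pair exceeds the relative cutoff.
    """
    reasons = []
    if report.first_eigenvalue >= eigen_cutoff:
        reasons.append(
            f"first residual eigenvalue {report.first_eigenvalue:.2f} >= "
            f"{eigen_cutoff:.1f}"
        )
    for a, b, r in report.flagged_pairs:
        reasons.append(
            f"residual correlation {a}-{b} = {r:.2f} exceeds relative cutoff "
            f"{report.cutoff:.2f}"
        )
    verdict = "multidimensional" if reasons else "unidimensional"
    if not reasons:
        reasons.append(
            f"all eigenvalues < {eigen_cutoff:.1f} (max "
            f"{report.first_eigenvalue:.2f}) and no residual correlation above "
            f"{report.cutoff:.2f}"
        )
    return verdict, reasons
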