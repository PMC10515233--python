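"""Item fit: standardized residuals, outfit/infit mean squares, ZSTD.

Residuals standardize each response against PCM moments on one of two
bases:

* ``basis="conditional"`` (default for fit statistics): moments of
  ``X_i`` given the person's raw score over their observed items,
  computed from the elementary symmetric functions.  These are the
  moments the conditional likelihood actually constrains, so the mean
  squares are centred at 1 under the model — the point-estimate version
  below is biased downward because estimating each person's location
  absorbs roughly one degree of freedom per person.
* ``basis="theta"``: moments at the estimated person location,
  ``z_pi = (x_pi - E[X_pi | theta_p]) / sqrt(Var(X_pi | theta_p))`` —
  the conventional basis for residual PCA and Q3 screening.

Outfit is the unweighted mean of ``z^2`` per item; infit weights by the
conditional variance (information).  Both are ~1 under model fit.  The
z-standardized forms (ZSTD) use the Wilson-Hilferty cube-root
transformation with the model-based variance of the mean square
(Wright-Masters form, built from the conditional fourth moments):

    outfit:  q^2 = sum_p(C_pi / W_pi^2) / N^2  -  1 / N
    infit:   q^2 = sum_p(C_pi - W_pi^2) / (sum_p W_pi)^2
    ZSTD     = (MSQ^{1/3} - 1) * (3 / q) + q / 3

with ``W`` the conditional variance and ``C`` the conditional fourth
central moment.  Because ZSTD grows with sample size, a subsampling
protocol (average ZSTD over many modest subsamples) is provided for
large-sample screening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ResponseMatrix
from .exceptions import InvalidArgumentError
from .model import ItemParameters
from .pcm import category_moments
from .persons import PersonEstimates

__all__ = [
    "ResidualMatrix",
    "FitTable",
    "residuals",
    "outfit_infit",
    "subsampled_zstd",
    "flag_misfit",
]

LOW_N = 10  # below this many observations a fit statistic gets a low-n warning


@dataclass
class ResidualMatrix:
    """Standardized residuals with cached conditional moments.

    Entries are NaN where the response is missing or the person is
    extreme (their residuals are degenerate and are excluded, as in
    conditional-estimation practice).
    """

    z: np.ndarray           # persons x items, NaN where undefined
    expectation: np.ndarray
    variance: np.ndarray
    kurtosis: np.ndarray    # fourth central moment C_pi
    item_ids: list[str]

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.z)


def _conditional_moment_tables(rm: ResponseMatrix, ip: ItemParameters):
    """Per-person conditional moments of X_i given raw score and item subset."""
    from .pcm import cumulative_thresholds, log_esf

    n, k = rm.data.shape
    E = np.full((n, k), np.nan)
    W = np.full((n, k), np.nan)
    C = np.full((n, k), np.nan)
    obs = ~rm.missing_mask
    beta = [cumulative_thresholds(ip.thresholds[ip.item_ids.index(i)])
            for i in rm.item_ids]
    raw = np.where(rm.missing_mask, 0, rm.data).sum(axis=1)

    cache: dict[tuple, dict] = {}
    for p in range(n):
        key = obs[p].tobytes()
        if key not in cache:
            items = np.flatnonzero(obs[p])
            log_eps = [-beta[j] for j in items]
            lg = log_esf(log_eps)
            lg_minus = [
                log_esf([log_eps[q] for q in range(len(items)) if q != pos])
                for pos in range(len(items))
            ]
            cache[key] = {"items": items, "lg": lg, "lg_minus": lg_minus,
                          "scores": {}}
        entry = cache[key]
        r = int(raw[p])
        if r not in entry["scores"]:
            items = entry["items"]
            moments = []
            for pos, j in enumerate(items):
                lm = entry["lg_minus"][pos]
                xs = np.arange(beta[j].size)
                lp = np.full(xs.size, -np.inf)
                for x in xs:
                    if 0 <= r - x < lm.size:
                        lp[x] = -beta[j][x] + lm[r - x] - entry["lg"][r]
                pr = np.exp(lp)
                mean = float(pr @ xs)
                d = xs - mean
                moments.append((mean, float(pr @ d**2), float(pr @ d**4)))
            entry["scores"][r] = moments
        for pos, j in enumerate(entry["items"]):
            E[p, j], W[p, j], C[p, j] = entry["scores"][r][pos]
    return E, W, C


def residuals(rm: ResponseMatrix, ip: ItemParameters,
              pe: PersonEstimates, basis: str = "conditional") -> ResidualMatrix:
    """Standardized response residuals on the requested moment basis."""
    if pe.theta.shape[0] != rm.n_persons:
        raise InvalidArgumentError("person estimates do not match the response matrix")
    if basis not in ("conditional", "theta"):
        raise InvalidArgumentError(f"unknown residual basis {basis!r}")
    if basis == "conditional":
        E, W, C = _conditional_moment_tables(rm, ip)
        use = ~pe.extreme
        z = np.where(
            use[:, None] & ~rm.missing_mask & (W > 0),
            (rm.data - E) / np.sqrt(np.where(W > 0, W, np.nan)),
            np.nan,
        )
        E = np.where(np.isfinite(z), E, np.nan)
        W = np.where(np.isfinite(z), W, np.nan)
        C = np.where(np.isfinite(z), C, np.nan)
        return ResidualMatrix(z=z, expectation=E, variance=W, kurtosis=C,
                              item_ids=list(rm.item_ids))
    n, k = rm.data.shape
    E = np.full((n, k), np.nan)
    W = np.full((n, k), np.nan)
    C = np.full((n, k), np.nan)
    z = np.full((n, k), np.nan)
    use_person = ~pe.extreme & np.isfinite(pe.theta)
    for j, iid in enumerate(rm.item_ids):
        th = ip.thresholds[ip.item_ids.index(iid)]
        rows = use_person & ~rm.missing_mask[:, j]
        mean, var, _, mu4 = category_moments(pe.theta[rows], th)
        E[rows, j] = mean
        W[rows, j] = var
        C[rows, j] = mu4
        z[rows, j] = (rm.data[rows, j] - mean) / np.sqrt(var)
    return ResidualMatrix(z=z, expectation=E, variance=W, kurtosis=C,
                          item_ids=list(rm.item_ids))


@dataclass
class FitTable:
    """Per-item outfit/infit mean squares and ZSTDs, with misfit flags."""

    table: pd.DataFrame  # index item; msq/zstd columns, n_obs, low_n

    def __repr__(self):
        return repr(self.table.round(3))

    def to_csv(self, path):
        self.table.to_csv(path)


def _zstd(msq: float, q2: float) -> float:
    if q2 <= 0:
        return np.nan
    q = np.sqrt(q2)
    return (np.cbrt(msq) - 1.0) * (3.0 / q) + q / 3.0


def outfit_infit(res: ResidualMatrix) -> FitTable:
    """Outfit/infit mean squares and Wilson-Hilferty ZSTDs per item."""
    if not np.any(res.defined):
        raise InvalidArgumentError("residual matrix is empty")
    rows = []
    for j, iid in enumerate(res.item_ids):
        ok = res.defined[:, j]
        n = int(ok.sum())
        z2 = res.z[ok, j] ** 2
        W = res.variance[ok, j]
        C = res.kurtosis[ok, j]
        outfit = float(np.mean(z2)) if n else np.nan
        infit = float(np.sum(z2 * W) / np.sum(W)) if n else np.nan
        q2_out = float(np.sum(C / W**2) / n**2 - 1.0 / n) if n else np.nan
        q2_in = float(np.sum(C - W**2) / np.sum(W) ** 2) if n else np.nan
        rows.append(
            {
                "item": iid,
                "outfit_msq": outfit,
                "infit_msq": infit,
                "outfit_zstd": _zstd(outfit, q2_out),
                "infit_zstd": _zstd(infit, q2_in),
                "n_obs": n,
                "low_n": n < LOW_N,
            }
        )
    table = pd.DataFrame(rows).set_index("item")
    return flag_misfit(FitTable(table=table))


def flag_misfit(ft: FitTable, msq_range=(0.7, 1.3), zstd_bound=2.0) -> FitTable:
    """Attach misfit flags; bounds are inclusive (MSQ of exactly 0.7 passes)."""
    t = ft.table.copy()
    lo, hi = msq_range
    for stat in ("outfit", "infit"):
        msq, zstd = t[f"{stat}_msq"], t[f"{stat}_zstd"]
        t[f"{stat}_msq_low"] = msq < lo
        t[f"{stat}_msq_high"] = msq > hi
        t[f"{stat}_zstd_low"] = zstd < -zstd_bound
        t[f"{stat}_zstd_high"] = zstd > zstd_bound
    flagcols = [c for c in t.columns if c.endswith(("_low", "_high")) and c != "low_n"]
    t["misfit"] = t[flagcols].any(axis=1)
    return FitTable(table=t)


def subsampled_zstd(rm: ResponseMatrix, ip: ItemParameters, k: int = 40,
                    n_sub: int = 300, seed: int | None = None,
                    refit: bool = False, method: str = "wle") -> pd.DataFrame:
    """Average ZSTD over ``k`` random subsamples of ``n_sub`` persons.

    Item parameters are held fixed from the full fit by default
    (``refit=True`` re-estimates them per subsample).  Deterministic for
    a fixed ``seed``.  Returns per-item mean and SD of both ZSTDs across
    subsamples.
    """
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if n_sub > rm.n_persons:
        raise InvalidArgumentError(
            f"n_sub={n_sub} exceeds the {rm.n_persons} available persons"
        )
    rng = np.random.default_rng(seed)
    acc = {iid: {"outfit_zstd": [], "infit_zstd": []} for iid in rm.item_ids}
    from .persons import estimate_persons

    res_full = None
    if not refit:
        # fixed parameters: per-person moments are subsample-invariant,
        # so compute the residual matrix once and resample its rows
        pe_full = estimate_persons(rm, ip, method=method)
        res_full = residuals(rm, ip, pe_full)
    for _ in range(k):
        idx = np.sort(rng.choice(rm.n_persons, size=n_sub, replace=False))
        if refit:
            sub = ResponseMatrix(
                data=rm.data[idx], missing_mask=rm.missing_mask[idx],
                item_meta=rm.item_meta, person_meta=rm.person_meta.iloc[idx],
            )
            from .model import fit_cml

            ip_sub = fit_cml(sub, compute_se=False).params
            pe = estimate_persons(sub, ip_sub, method=method)
            ft = outfit_infit(residuals(sub, ip_sub, pe))
        else:
            ft = outfit_infit(ResidualMatrix(
                z=res_full.z[idx], expectation=res_full.expectation[idx],
                variance=res_full.variance[idx], kurtosis=res_full.kurtosis[idx],
                item_ids=res_full.item_ids,
            ))
        for iid in rm.item_ids:
            for col in ("outfit_zstd", "infit_zstd"):
                acc[iid][col].append(ft.table.loc[iid, col])
    rows = []
    for iid in rm.item_ids:
        rows.append(
            {
                "item": iid,
                "outfit_zstd_mean": float(np.mean(acc[iid]["outfit_zstd"])),
                "outfit_zstd_sd": float(np.std(acc[iid]["outfit_zstd"], ddof=0)),
                "infit_zstd_mean": float(np.mean(acc[iid]["infit_zstd"])),
                "infit_zstd_sd": float(np.std(acc[iid]["infit_zstd"], ddof=0)),
                "k": k,
                "n_sub": n_sub,
            }
        )
    return pd.DataFrame(rows).set_index("item")
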