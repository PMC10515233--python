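"""Partial credit model estimation by conditional maximum likelihood.

``PartialCreditModel`` is constructed from a :class:`~raschpcm.data.ResponseMatrix`
(or a DataFrame) and its :meth:`~PartialCreditModel.fit` returns a
:class:`PCMResults` object carrying item step thresholds, their standard
errors, convergence diagnostics and a ``summary()`` table, in the style of
statsmodels model/results pairs.

Estimation conditions on each person's raw score, which eliminates the
person parameters: the conditional likelihood of a response pattern with
total score ``r`` over observed items ``S`` is

    prod_{i in S} exp(-beta_{i, x_i}) / gamma_r(S)

where ``beta_{i,x} = sum_{k<=x} delta_{i,k}`` are cumulative step
parameters and ``gamma_r`` the elementary symmetric functions.  Persons
with extreme raw scores (zero or maximum) carry no information about the
items and are excluded; persons are grouped by observed-item subset so
missing responses are handled exactly.

Identification: the conditional likelihood is flat along the direction
``beta_{i,x} += c * x`` (a common shift of all item locations).  The fit
pins it down with the convention that item locations (mean step threshold
per item) sum to zero, enforced through an exact quadratic penalty on the
flat direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .data import ResponseMatrix
from .exceptions import ConvergenceError, DataError
from .pcm import expected_score as _expected_score
from .pcm import log_esf, test_information as _test_information

__all__ = ["PartialCreditModel", "PCMResults", "ItemParameters", "fit_cml"]


@dataclass
class ItemParameters:
    """Estimated PCM step thresholds per item, with the identification tag.

    ``thresholds[i]`` is the ordered sequence ``delta_{i,1..m_i}`` in
    logits; ``item_location`` is the mean of an item's thresholds.  The
    ``normalization`` tag records the constraint that identified the
    metric so reports can re-anchor.
    """

    item_ids: list[str]
    thresholds: list[np.ndarray]
    se_thresholds: list[np.ndarray] | None = None
    normalization: str = "sum_of_item_locations_zero"

    @property
    def item_locations(self) -> np.ndarray:
        return np.array([float(np.mean(t)) for t in self.thresholds])

    @property
    def max_categories(self) -> np.ndarray:
        return np.array([t.size for t in self.thresholds])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iid, th, loc in zip(self.item_ids, self.thresholds, self.item_locations):
            row = {"item": iid, "location": loc}
            row.update({f"delta_{k + 1}": v for k, v in enumerate(th)})
            rows.append(row)
        return pd.DataFrame(rows).set_index("item")

    def subset(self, item_ids) -> "ItemParameters":
        idx = [self.item_ids.index(i) for i in item_ids]
        return ItemParameters(
            item_ids=[self.item_ids[i] for i in idx],
            thresholds=[self.thresholds[i] for i in idx],
            se_thresholds=None
            if self.se_thresholds is None
            else [self.se_thresholds[i] for i in idx],
            normalization=self.normalization + " (of parent fit)",
        )

    def shifted(self, offset: float) -> "ItemParameters":
        """Add a constant to every threshold (re-anchoring to another metric)."""
        return ItemParameters(
            item_ids=list(self.item_ids),
            thresholds=[t + offset for t in self.thresholds],
            se_thresholds=self.se_thresholds,
            normalization=f"shifted by {offset:+.4f} from {self.normalization}",
        )


class _CMLProblem:
    """Sufficient statistics and ESF bookkeeping for one data set."""

    def __init__(self, rm: ResponseMatrix):
        data, mask, recodings = _preprocess(rm)
        self.recodings = recodings
        self.m = np.array([int(data[:, j][~mask[:, j]].max(initial=0)) for j in
                           range(data.shape[1])])
        obs = ~mask
        raw = np.where(mask, 0, data).sum(axis=1)
        maxraw = (self.m * obs).sum(axis=1)
        nonextreme = (raw > 0) & (raw < maxraw) & (obs.sum(axis=1) > 0)
        self.extreme_excluded = int((~nonextreme).sum())
        if nonextreme.sum() < 2:
            raise DataError("fewer than 2 non-extreme persons; nothing to estimate")

        self.n_items = data.shape[1]
        self.n_used = int(nonextreme.sum())
        # slices of the beta parameter vector per item
        self.offsets = np.concatenate([[0], np.cumsum(self.m)])
        self.n_params = int(self.m.sum())

        # sufficient statistics: counts of non-extreme responses per item x category
        self.n_ix = [np.zeros(mi + 1) for mi in self.m]
        d, o = data[nonextreme], obs[nonextreme]
        for j in range(self.n_items):
            col = d[:, j][o[:, j]]
            self.n_ix[j] = np.bincount(col, minlength=self.m[j] + 1).astype(float)

        # group persons by observed-item subset, then count raw scores
        self.groups: list[tuple[tuple[int, ...], np.ndarray]] = []
        keys = {}
        r_used = raw[nonextreme]
        for p in range(d.shape[0]):
            key = o[p].tobytes()
            if key not in keys:
                keys[key] = tuple(np.flatnonzero(o[p]))
        for key, items in keys.items():
            sel = np.array([o[p].tobytes() == key for p in range(d.shape[0])])
            scores = r_used[sel]
            maxs = int(self.m[list(items)].sum())
            counts = np.bincount(scores, minlength=maxs + 1).astype(float)
            self.groups.append((items, counts))

    def unpack(self, beta: np.ndarray) -> list[np.ndarray]:
        """Per-item cumulative parameters including beta_{i,0} = 0."""
        return [
            np.concatenate([[0.0], beta[self.offsets[j]: self.offsets[j + 1]]])
            for j in range(self.n_items)
        ]

    def nll_grad(self, beta: np.ndarray) -> tuple[float, np.ndarray]:
        """Negative conditional log-likelihood (per person) and its gradient."""
        b = self.unpack(beta)
        nll = sum(float(self.n_ix[j][1:] @ beta[self.offsets[j]: self.offsets[j + 1]])
                  for j in range(self.n_items))
        grad = np.concatenate([self.n_ix[j][1:] for j in range(self.n_items)])

        for items, counts in self.groups:
            scores = np.flatnonzero(counts)
            if scores.size == 0:
                continue
            log_eps = [-b[j] for j in items]
            lg = log_esf(log_eps)
            nll += float(counts[scores] @ lg[scores])
            # gradient: observed minus conditionally expected counts
            for pos, j in enumerate(items):
                lg_minus = log_esf([log_eps[q] for q in range(len(items)) if q != pos])
                for x in range(1, self.m[j] + 1):
                    tot = 0.0
                    for r in scores:
                        rx = r - x
                        if 0 <= rx < lg_minus.size:
                            tot += counts[r] * np.exp(-b[j][x] + lg_minus[rx] - lg[r])
                    grad[self.offsets[j] + x - 1] -= tot
        return nll / self.n_used, grad / self.n_used

    # direction of the likelihood's exact flat ray: beta_{i,x} += c * x
    def location_vector(self) -> np.ndarray:
        """Gradient of sum of item locations w.r.t. beta (for the penalty)."""
        v = np.zeros(self.n_params)
        for j in range(self.n_items):
            v[self.offsets[j + 1] - 1] = 1.0 / self.m[j]
        return v


def _preprocess(rm: ResponseMatrix):
    """Relabel each item's observed categories consecutively (collapse nulls).

    A category with zero observations is merged into its lower neighbour
    so the conditional likelihood stays well-defined; the recoding is
    returned for the run log.
    """
    data = rm.data.copy()
    mask = rm.missing_mask
    recodings = {}
    for j, iid in enumerate(rm.item_ids):
        col = data[:, j][~mask[:, j]]
        if col.size == 0 or np.unique(col).size < 2:
            raise DataError(
                f"item {iid!r} has fewer than 2 observed categories; "
                "drop or merge it before fitting"
            )
        seen = np.unique(col)
        want = np.arange(seen.size)
        if not np.array_equal(seen, want):
            lut = {int(s): int(w) for s, w in zip(seen, want)}
            newcol = np.array([lut[int(v)] for v in data[:, j]])
            data[:, j] = np.where(mask[:, j], data[:, j], newcol)
            recodings[iid] = lut
    return data, mask, recodings


class PartialCreditModel:
    """Rasch partial credit model for a polytomous response matrix.

    Parameters
    ----------
    responses : ResponseMatrix
        Persons x items integer categories with missing mask and metadata.

    Examples
    --------
    >>> model = PartialCreditModel.from_dataframe(df)
    >>> res = model.fit()
    >>> res.params.item_locations
    """

    def __init__(self, responses: ResponseMatrix):
        self.responses = responses

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, item_meta=None, person_meta=None):
        return cls(ResponseMatrix.from_dataframe(df, item_meta=item_meta,
                                                 person_meta=person_meta))

    def fit(self, tol: float = 1e-8, max_iter: int = 200,
            compute_se: bool = True, start=None) -> "PCMResults":
        """Estimate step thresholds by conditional maximum likelihood.

        ``tol`` is the target infinity-norm of the per-person gradient; a
        quasi-Newton (BFGS) iteration with the analytic gradient is used.
        Raises :class:`ConvergenceError` when the gradient norm remains
        above ``1e-4`` after ``max_iter`` iterations.
        """
        prob = _CMLProblem(self.responses)
        v = prob.location_vector()

        def objective(beta):
            f, g = prob.nll_grad(beta)
            s = float(v @ beta)  # sum of item locations
            return f + s * s, g + 2.0 * s * v

        x0 = np.zeros(prob.n_params) if start is None else np.asarray(start, float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # BFGS precision-loss noise near optimum
            res = optimize.minimize(
                objective, x0, jac=True, method="BFGS",
                options={"gtol": tol, "maxiter": max_iter},
            )
        grad_norm = float(np.max(np.abs(res.jac)))
        if grad_norm > 1e-4:
            raise ConvergenceError(
                f"conditional ML did not converge: gradient norm {grad_norm:.3e} "
                f"after {res.nit} iterations"
            )
        beta = res.x

        cov = None
        if compute_se:
            cov = _covariance(objective, beta, scale=prob.n_used)

        return PCMResults(
            model=self, _problem=prob, beta=beta, cov_beta=cov,
            loglike=-float(prob.nll_grad(beta)[0]) * prob.n_used,
            converged=grad_norm <= max(tol * 10, 1e-6),
            grad_norm=grad_norm, n_iter=int(res.nit),
        )


def _covariance(objective, beta, scale, h=1e-5):
    """Observed-information covariance by central differences of the gradient."""
    k = beta.size
    H = np.zeros((k, k))
    for i in range(k):
        e = np.zeros(k)
        e[i] = h
        _, gp = objective(beta + e)
        _, gm = objective(beta - e)
        H[i] = (gp - gm) / (2 * h)
    H = scale * (H + H.T) / 2.0
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:  # pragma: no cover - pathological data
        return np.linalg.pinv(H)


@dataclass
class PCMResults:
    """Fitted PCM: thresholds, uncertainties, diagnostics and analysis entry points.

    The analysis stages (item fit, dimensionality, DIF, reliability,
    score conversion) are available as methods so a fitted results object
    is the hub of the whole evaluation.
    """

    model: PartialCreditModel
    _problem: _CMLProblem
    beta: np.ndarray
    cov_beta: np.ndarray | None
    loglike: float
    converged: bool
    grad_norm: float
    n_iter: int
    _params: ItemParameters | None = field(default=None, repr=False)

    # -- parameters ---------------------------------------------------
    @property
    def params(self) -> ItemParameters:
        if self._params is None:
            prob = self._problem
            ths, ses = [], []
            for j in range(prob.n_items):
                sl = slice(prob.offsets[j], prob.offsets[j + 1])
                bj = np.concatenate([[0.0], self.beta[sl]])
                ths.append(np.diff(bj))
                if self.cov_beta is not None:
                    # delta: delta_k = beta_k - beta_{k-1}
                    m = prob.m[j]
                    D = np.zeros((m, prob.n_params))
                    for k in range(m):
                        D[k, prob.offsets[j] + k] = 1.0
                        if k > 0:
                            D[k, prob.offsets[j] + k - 1] = -1.0
                    ses.append(np.sqrt(np.diag(D @ self.cov_beta @ D.T)))
            self._params = ItemParameters(
                item_ids=list(self.model.responses.item_ids),
                thresholds=ths,
                se_thresholds=ses if self.cov_beta is not None else None,
            )
        return self._params

    @property
    def recodings(self) -> dict:
        """Category relabelings applied before fitting (empty if none)."""
        return self._problem.recodings

    @property
    def n_used(self) -> int:
        return self._problem.n_used

    @property
    def n_extreme_excluded(self) -> int:
        return self._problem.extreme_excluded

    def df_model(self) -> int:
        """Free item parameters under the location constraint."""
        return self._problem.n_params - 1

    # -- derived quantities -------------------------------------------
    def _thresholds_for(self, items=None) -> list[np.ndarray]:
        p = self.params
        ids = p.item_ids if items is None else list(items)
        return [p.thresholds[p.item_ids.index(i)] for i in ids]

    def expected_score(self, theta, items=None):
        """Expected raw sum score at ``theta`` over an item subset."""
        return _expected_score(theta, self._thresholds_for(items))

    def test_information(self, theta, items=None):
        """Test information function at ``theta`` over an item subset."""
        return _test_information(theta, self._thresholds_for(items))

    # -- analysis stages ----------------------------------------------
    def person_estimates(self, method: str = "wle"):
        from .persons import estimate_persons

        return estimate_persons(self.model.responses, self.params, method=method)

    def residuals(self, person_estimates=None, basis: str = "conditional"):
        from .item_fit import residuals

        pe = person_estimates or self.person_estimates()
        return residuals(self.model.responses, self.params, pe, basis=basis)

    def item_fit(self, person_estimates=None):
        from .item_fit import outfit_infit

        return outfit_infit(self.residuals(person_estimates, basis="conditional"))

    def dimensionality(self, person_estimates=None):
        from .dimensionality import dimensionality_report

        return dimensionality_report(
            self.residuals(person_estimates, basis="theta"))

    def reliability(self, psi_threshold: float = 0.7, person_estimates=None):
        from .targeting_reliability import reliability_profile

        pe = person_estimates or self.person_estimates()
        return reliability_profile(self.params, pe, psi_threshold=psi_threshold)

    def targeting(self, person_estimates=None):
        from .targeting_reliability import targeting_summary

        pe = person_estimates or self.person_estimates()
        return targeting_summary(pe, self.params)

    def score_table(self, items=None):
        from .score_transform import score_to_theta_table

        ids = self.params.item_ids if items is None else list(items)
        return score_to_theta_table(self.params, ids)

    # -- reporting ----------------------------------------------------
    def summary(self) -> str:
        p = self.params
        lines = [
            "Partial Credit Model (conditional maximum likelihood)",
            "=" * 72,
            f"Persons used: {self.n_used}   (extreme excluded: "
            f"{self.n_extreme_excluded})",
            f"Items: {len(p.item_ids)}   Free parameters: {self.df_model()}",
            f"Conditional log-likelihood: {self.loglike:.3f}",
            f"Converged: {self.converged}  (|grad| = {self.grad_norm:.2e}, "
            f"{self.n_iter} iterations)",
            f"Normalization: {p.normalization}",
            "-" * 72,
            f"{'item':<8}{'location':>10}  thresholds (SE)",
        ]
        for j, iid in enumerate(p.item_ids):
            th = p.thresholds[j]
            if p.se_thresholds is not None:
                cells = ", ".join(
                    f"{t:.3f} ({s:.3f})" for t, s in zip(th, p.se_thresholds[j])
                )
            else:
                cells = ", ".join(f"{t:.3f}" for t in th)
            lines.append(f"{iid:<8}{p.item_locations[j]:>10.3f}  {cells}")
        if self.recodings:
            lines.append("-" * 72)
            lines.append(f"Category recodings applied: {self.recodings}")
        return "\n".join(lines)


def fit_cml(rm: ResponseMatrix, tol: float = 1e-8, max_iter: int = 200,
            compute_se: bool = True) -> PCMResults:
    """Functional entry point: fit a PCM to ``rm`` by CML."""
    return PartialCreditModel(rm).fit(tol=tol, max_iter=max_iter,
                                      compute_se=compute_se)
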