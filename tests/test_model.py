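"""CML estimation and person ability estimation."""

import numpy as np
import pandas as pd
import pytest

from conftest import centered_true_thresholds
from raschpcm import (
    ItemParameters,
    PartialCreditModel,
    ResponseMatrix,
    estimate_persons,
    simulate_pcm,
)
from raschpcm.exceptions import DataError, UndefinedPersonError
from raschpcm.synthetic_data import SimulationSpec


def _spec(thresholds, n, seed, mean=0.0, sd=1.0, **kw):
    return SimulationSpec(n_persons=n, thresholds=thresholds, person_mean=mean,
                          person_sd=sd, seed=seed, **kw)


class TestFitCML:
    def test_parameter_recovery(self, uni_fit):
        rm, truth, res = uni_fit
        est = np.concatenate(res.params.thresholds)
        true = np.concatenate(centered_true_thresholds(truth, res.params.item_ids))
        rmse = np.sqrt(np.mean((est - true) ** 2))
        assert rmse < 0.15

    def test_item_locations_sum_to_zero(self, uni_fit):
        _, _, res = uni_fit
        assert abs(res.params.item_locations.sum()) < 1e-6

    def test_convergence_report(self, uni_fit):
        _, _, res = uni_fit
        assert res.converged
        assert res.grad_norm < 1e-6
        assert 0 < res.n_iter <= 200
        assert res.loglike < 0

    def test_identical_items_agree_within_2se(self):
        th = {"i1": np.array([-1.0, -0.3, 0.3, 1.0]),
              "i2": np.array([-1.0, -0.3, 0.3, 1.0])}
        rm, _ = simulate_pcm(_spec(th, n=2000, seed=9, sd=1.5))
        res = PartialCreditModel(rm).fit()
        p = res.params
        gap = np.abs(p.thresholds[0] - p.thresholds[1])
        se = np.sqrt(p.se_thresholds[0] ** 2 + p.se_thresholds[1] ** 2)
        assert np.all(gap < 2.0 * se)

    def test_shift_invariance_of_cml(self):
        # shifting the simulating person distribution must not move the
        # item estimates (beyond Monte-Carlo error) - the point of CML
        ths = {f"i{j}": np.array([-1.2, -0.4, 0.4, 1.2]) + mu
               for j, mu in enumerate(np.linspace(-1, 1, 6))}
        est = []
        for seed, mean in ((21, 0.0), (22, 1.0)):
            rm, _ = simulate_pcm(_spec(ths, n=2000, seed=seed, mean=mean, sd=1.5))
            est.append(np.concatenate(
                PartialCreditModel(rm).fit(compute_se=False).params.thresholds))
        assert np.sqrt(np.mean((est[0] - est[1]) ** 2)) < 0.15

    def test_empty_category_collapsed_and_logged(self):
        # category 2 never observed: it merges into its lower neighbour
        rng = np.random.default_rng(0)
        data = rng.integers(0, 2, size=(300, 2)) * 3  # only codes 0 and 3
        data[:150, 1] = rng.integers(0, 4, size=150)
        meta = pd.DataFrame({"polarity": "negative", "max_category": 3},
                            index=pd.Index(["a", "b"], name="id"))
        rm = ResponseMatrix(data=data, missing_mask=None, item_meta=meta)
        res = PartialCreditModel(rm).fit(compute_se=False)
        assert "a" in res.recodings
        assert res.params.thresholds[0].size == 1  # collapsed to dichotomous

    def test_degenerate_item_rejected(self):
        data = np.zeros((50, 2), dtype=int)
        data[:, 1] = np.arange(50) % 3
        meta = pd.DataFrame({"polarity": "negative", "max_category": 2},
                            index=pd.Index(["a", "b"], name="id"))
        rm = ResponseMatrix(data=data, missing_mask=None, item_meta=meta)
        with pytest.raises(DataError, match="fewer than 2 observed categories"):
            PartialCreditModel(rm).fit()

    def test_missing_data_grouped_by_subset(self):
        spec = _spec({f"i{j}": np.array([-0.8, 0.0, 0.8]) for j in range(5)},
                     n=1500, seed=7, sd=1.2)
        spec.missing_rate = 0.15
        rm, truth = simulate_pcm(spec)
        res = PartialCreditModel(rm).fit(compute_se=False)
        est = np.concatenate(res.params.thresholds)
        true = np.concatenate(centered_true_thresholds(truth, res.params.item_ids))
        assert np.sqrt(np.mean((est - true) ** 2)) < 0.2


class TestPersonEstimation:
    def test_monotone_in_raw_score(self, uni_fit, uni_persons):
        rm, _, _ = uni_fit
        pe = uni_persons
        complete = ~rm.missing_mask.any(axis=1)
        df = pe.to_frame()[complete].sort_values("raw_score")
        theta_by_score = df.groupby("raw_score")["theta"].first()
        assert np.all(np.diff(theta_by_score.to_numpy()) > 0)
        assert theta_by_score.index.min() == 0  # extremes located too (WLE)

    def test_symmetric_instrument_centre_score_at_zero(self):
        ip = ItemParameters(item_ids=["a", "b"],
                            thresholds=[np.array([-1.5, -0.5, 0.5, 1.5]),
                                        np.array([-2.0, -1.0, 1.0, 2.0])])
        data = np.array([[2, 2], [0, 1]])
        rm = ResponseMatrix(
            data=data, missing_mask=None,
            item_meta=pd.DataFrame({"polarity": "negative", "max_category": 4},
                                   index=pd.Index(["a", "b"], name="id")),
        )
        pe = estimate_persons(rm, ip, method="mle")
        assert pe.theta[0] == pytest.approx(0.0, abs=1e-8)

    def test_theta_recovery_correlation(self):
        ths = {f"i{j}": np.array([-1.2, -0.4, 0.4, 1.2]) + mu
               for j, mu in enumerate(np.linspace(-0.8, 0.8, 7))}
        rm, truth = simulate_pcm(_spec(ths, n=2000, seed=17, sd=1.5))
        res = PartialCreditModel(rm).fit(compute_se=False)
        pe = res.person_estimates()
        r = np.corrcoef(pe.theta, truth["theta"][:, 0])[0, 1]
        assert r > 0.9

    def test_extremes_flagged_and_finite_under_wle(self, uni_fit, uni_persons):
        pe = uni_persons
        assert np.all(np.isfinite(pe.theta))
        assert np.all(pe.se > 0)
        assert np.array_equal(pe.extreme,
                              (pe.raw_score == 0) | (pe.raw_score == 56))

    def test_mle_extremes_infinite(self, uni_fit):
        rm, _, res = uni_fit
        pe = res.person_estimates(method="mle")
        ext = pe.extreme
        if ext.any():
            assert np.all(np.isinf(pe.theta[ext]))
        assert np.all(np.isfinite(pe.theta[~ext]))

    def test_person_without_responses_rejected(self, uni_fit):
        rm, _, res = uni_fit
        mask = rm.missing_mask.copy()
        mask[0, :] = True
        broken = ResponseMatrix(data=rm.data, missing_mask=mask,
                                item_meta=rm.item_meta, person_meta=rm.person_meta)
        with pytest.raises(UndefinedPersonError):
            estimate_persons(broken, res.params)


class TestResultsObject:
    def test_summary_renders(self, uni_fit):
        _, _, res = uni_fit
        s = res.summary()
        assert "conditional maximum likelihood" in s.lower()
        assert all(iid in s for iid in res.params.item_ids)

    def test_expected_score_and_information_delegation(self, uni_fit):
        _, _, res = uni_fit
        sub = res.params.item_ids[:3]
        es = res.expected_score(0.0, items=sub)
        assert 0 < float(es) < 12
        assert float(res.test_information(0.0, items=sub)) > 0

    def test_params_frame_shape(self, uni_fit):
        _, _, res = uni_fit
        df = res.params.to_frame()
        assert list(df.columns)[:1] == ["location"]
        assert len(df) == 14
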