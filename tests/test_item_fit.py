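"""Fit statistics: residuals, mean squares, ZSTD and the subsample protocol."""

import numpy as np
import pandas as pd
import pytest

from raschpcm import (
    FitTable,
    PartialCreditModel,
    ResponseMatrix,
    flag_misfit,
    outfit_infit,
    residuals,
    simulate_pcm,
    subsampled_zstd,
)
from raschpcm.exceptions import InvalidArgumentError
from raschpcm.item_fit import ResidualMatrix


class TestResiduals:
    def test_zero_residual_when_response_equals_expectation(self):
        z = np.array([[0.0, 0.3], [0.1, 0.0]])
        rm = ResidualMatrix(z=z, expectation=z * 0, variance=z * 0 + 1,
                            kurtosis=z * 0 + 3, item_ids=["a", "b"])
        assert rm.z[0, 0] == 0.0

    def test_null_mean_and_variance(self, uni_fit, uni_persons):
        rm, _, res = uni_fit
        r = residuals(rm, res.params, uni_persons)
        assert np.all(np.abs(np.nanmean(r.z, axis=0)) < 0.05)
        assert np.all(np.abs(np.nanvar(r.z, axis=0) - 1.0) < 0.12)

    def test_extreme_persons_excluded(self, uni_fit, uni_persons):
        rm, _, res = uni_fit
        r = residuals(rm, res.params, uni_persons)
        assert np.all(np.isnan(r.z[uni_persons.extreme]))

    def test_theta_basis_available(self, uni_fit, uni_persons):
        rm, _, res = uni_fit
        r = residuals(rm, res.params, uni_persons, basis="theta")
        assert np.all(np.abs(np.nanmean(r.z, axis=0)) < 0.05)

    def test_shape_mismatch_rejected(self, uni_fit, uni_persons):
        rm, _, res = uni_fit
        from raschpcm.persons import PersonEstimates

        short = PersonEstimates(theta=uni_persons.theta[:10],
                                se=uni_persons.se[:10],
                                raw_score=uni_persons.raw_score[:10],
                                extreme=uni_persons.extreme[:10], method="wle")
        with pytest.raises(InvalidArgumentError):
            residuals(rm, res.params, short)


class TestOutfitInfit:
    def test_null_mean_squares_near_one(self, uni_fit, uni_persons):
        _, _, res = uni_fit
        t = res.item_fit(uni_persons).table
        assert t["outfit_msq"].between(0.9, 1.1).all()
        assert t["infit_msq"].between(0.9, 1.1).all()

    def test_all_zero_residuals_give_msq_zero_and_underfit_flag(self):
        n = 50
        rm = ResidualMatrix(
            z=np.zeros((n, 2)), expectation=np.zeros((n, 2)),
            variance=np.full((n, 2), 0.8), kurtosis=np.full((n, 2), 1.0),
            item_ids=["a", "b"],
        )
        t = outfit_infit(rm).table
        assert (t["outfit_msq"] == 0).all()
        assert t["outfit_msq_low"].all()
        assert t["misfit"].all()

    def test_misfitting_item_detected(self, uni_fit):
        # drive one item by an independent trait: its MSQ must blow past 1.3
        rm, truth, _ = uni_fit
        rng = np.random.default_rng(99)
        data = rm.data.copy()
        alien = rng.normal(0.9, 1.6, size=rm.n_persons)
        from raschpcm.pcm import category_probability

        th = truth["thresholds"]["q7"]
        p = category_probability(alien, th)
        j = rm.item_ids.index("q7")
        data[:, j] = (p.cumsum(axis=1) < rng.random((rm.n_persons, 1))).sum(axis=1)
        broken = ResponseMatrix(data=data, missing_mask=rm.missing_mask,
                                item_meta=rm.item_meta, person_meta=rm.person_meta)
        res = PartialCreditModel(broken).fit(compute_se=False)
        t = res.item_fit().table
        assert t.loc["q7", "outfit_msq"] > 1.3
        assert t.loc["q7", "misfit"]

    def test_low_n_flag(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(6, 2))
        rm = ResidualMatrix(z=z, expectation=z * 0, variance=z * 0 + 1,
                            kurtosis=z * 0 + 3, item_ids=["a", "b"])
        assert outfit_infit(rm).table["low_n"].all()

    def test_empty_residuals_rejected(self):
        rm = ResidualMatrix(z=np.full((4, 2), np.nan),
                            expectation=np.full((4, 2), np.nan),
                            variance=np.full((4, 2), np.nan),
                            kurtosis=np.full((4, 2), np.nan), item_ids=["a", "b"])
        with pytest.raises(InvalidArgumentError):
            outfit_infit(rm)


class TestFlagMisfit:
    def _table(self, **kw):
        row = {"outfit_msq": 1.0, "infit_msq": 1.0, "outfit_zstd": 0.0,
               "infit_zstd": 0.0, "n_obs": 100, "low_n": False}
        row.update(kw)
        return FitTable(table=pd.DataFrame([row], index=pd.Index(["a"], name="item")))

    def test_perfect_fit_unflagged(self):
        t = flag_misfit(self._table()).table
        assert not t["misfit"].iloc[0]

    def test_boundary_is_inclusive(self):
        # MSQ of exactly 0.7 (or 1.3) is inside the acceptable range
        t = flag_misfit(self._table(outfit_msq=0.7, infit_msq=1.3)).table
        assert not t["misfit"].iloc[0]

    @pytest.mark.parametrize(
        "kw,col",
        [({"outfit_msq": 0.638}, "outfit_msq_low"),
         ({"infit_msq": 1.31}, "infit_msq_high"),
         ({"outfit_zstd": -2.5}, "outfit_zstd_low"),
         ({"infit_zstd": 2.01}, "infit_zstd_high")],
    )
    def test_each_flag_direction(self, kw, col):
        t = flag_misfit(self._table(**kw)).table
        assert t[col].iloc[0]
        assert t["misfit"].iloc[0]


class TestSubsampledZSTD:
    def test_degenerate_subsample_equals_plain_zstd(self, uni_fit, uni_persons):
        rm, _, res = uni_fit
        full = res.item_fit(uni_persons).table
        d = subsampled_zstd(rm, res.params, k=1, n_sub=rm.n_persons, seed=0)
        assert np.allclose(d["outfit_zstd_mean"], full["outfit_zstd"])
        assert np.allclose(d["infit_zstd_mean"], full["infit_zstd"])

    def test_deterministic_under_seed(self, uni_fit):
        rm, _, res = uni_fit
        a = subsampled_zstd(rm, res.params, k=5, n_sub=300, seed=42)
        b = subsampled_zstd(rm, res.params, k=5, n_sub=300, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_null_average_within_bounds(self, uni_fit):
        rm, _, res = uni_fit
        d = subsampled_zstd(rm, res.params, k=40, n_sub=300, seed=11)
        assert np.all(np.abs(d["outfit_zstd_mean"]) < 2)
        assert np.all(np.abs(d["infit_zstd_mean"]) < 2)

    def test_shrinks_large_sample_inflation(self, uni_fit, uni_persons):
        # averaged subsample ZSTD is closer to 0 than the full-sample value
        rm, _, res = uni_fit
        full = res.item_fit(uni_persons).table
        d = subsampled_zstd(rm, res.params, k=20, n_sub=300, seed=7)
        worst_full = np.abs(full["outfit_zstd"]).max()
        worst_sub = np.abs(d["outfit_zstd_mean"]).max()
        assert worst_sub < worst_full

    def test_oversized_subsample_rejected(self, uni_fit):
        rm, _, res = uni_fit
        with pytest.raises(InvalidArgumentError):
            subsampled_zstd(rm, res.params, k=2, n_sub=rm.n_persons + 1, seed=0)
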