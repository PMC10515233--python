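"""Threshold ordering, targeting summaries and conditional reliability."""

import numpy as np
import pytest

from raschpcm import (
    ItemParameters,
    PartialCreditModel,
    information_for_psi,
    ordered_thresholds_check,
    psi_from_information,
    reliability_profile,
    simulate_pcm,
    targeting_summary,
)
from raschpcm.exceptions import InvalidArgumentError
from raschpcm.pcm import category_probability
from raschpcm.persons import PersonEstimates
from raschpcm.synthetic_data import SimulationSpec


class TestPSIInformationRelation:
    def test_psi_point_seven_is_ti_ten_thirds(self):
        assert psi_from_information(10.0 / 3.0) == pytest.approx(0.7, abs=1e-12)
        assert information_for_psi(0.7) == pytest.approx(10.0 / 3.0, rel=1e-9)

    def test_psi_point_eight_is_ti_five(self):
        assert psi_from_information(5.0) == pytest.approx(0.8, abs=1e-12)
        assert information_for_psi(0.8) == pytest.approx(5.0, rel=1e-9)

    def test_clipped_below_unit_information(self):
        assert psi_from_information(0.5) == 0.0

    def test_invalid_psi_rejected(self):
        with pytest.raises(InvalidArgumentError):
            information_for_psi(1.0)


class TestOrderedThresholds:
    def test_ordered_set_unflagged(self):
        ip = ItemParameters(item_ids=["a"], thresholds=[np.array([-2., -1., 0., 1.])])
        t = ordered_thresholds_check(ip)
        assert not t.loc["a", "disordered"]

    def test_disordered_pair_located(self):
        ip = ItemParameters(item_ids=["a"],
                            thresholds=[np.array([-1.0, 0.5, 0.2, 1.0])])
        t = ordered_thresholds_check(ip)
        assert t.loc["a", "disordered"]
        assert t.loc["a", "first_bad_pair"] == "(2,3)"
        assert t.loc["a", "gap"] == pytest.approx(-0.3)

    def test_rare_middle_category_usually_flagged(self):
        # generating thresholds with a reversal starve the middle category;
        # the fitted item should show disordered thresholds in most runs
        ths = {"x": np.array([1.2, -1.2]),
               **{f"f{j}": np.array([-0.8, 0.8]) for j in range(5)}}
        flagged = 0
        for seed in range(3):
            spec = SimulationSpec(n_persons=800, thresholds=ths, person_sd=1.5,
                                  seed=60 + seed)
            rm, _ = simulate_pcm(spec)
            res = PartialCreditModel(rm).fit(compute_se=False)
            t = ordered_thresholds_check(res.params)
            flagged += bool(t.loc["x", "disordered"])
        assert flagged >= 2


class TestTargeting:
    def test_centered_simulation_recovers_zero_mean(self):
        ths = {f"i{j}": np.array([-1.0, 0.0, 1.0]) + mu
               for j, mu in enumerate(np.linspace(-0.9, 0.9, 7))}
        spec = SimulationSpec(n_persons=2000, thresholds=ths, person_mean=0.0,
                              person_sd=1.0, seed=71)
        rm, _ = simulate_pcm(spec)
        res = PartialCreditModel(rm).fit(compute_se=False)
        ts = res.targeting()
        assert ts.person_mean == pytest.approx(0.0, abs=0.1)
        assert ts.item_location_mean == pytest.approx(0.0, abs=1e-8)

    def test_single_person_sd_missing_with_warning(self):
        ip = ItemParameters(item_ids=["a"], thresholds=[np.array([0.0])])
        pe = PersonEstimates(theta=np.array([0.3]), se=np.array([1.0]),
                             raw_score=np.array([1]),
                             extreme=np.array([True]), method="wle")
        ts = targeting_summary(pe, ip)
        assert np.isnan(ts.person_sd)
        assert ts.warnings


class TestReliabilityProfile:
    def test_partition_sums_to_hundred(self, uni_fit, uni_persons):
        _, _, res = uni_fit
        prof = res.reliability(0.7, uni_persons)
        assert prof.pct_inside + prof.pct_above + prof.pct_below == pytest.approx(
            100.0, abs=0.1)
        assert prof.intervals

    def test_coverage_consistent_with_person_estimates(self, uni_fit, uni_persons):
        _, _, res = uni_fit
        prof = res.reliability(0.7, uni_persons)
        a, b = prof.intervals[0]
        theta = uni_persons.theta
        assert prof.pct_inside == pytest.approx(
            100.0 * np.mean((theta >= a) & (theta <= b)), abs=1e-9)

    def test_empty_interval_when_information_low(self):
        ip = ItemParameters(item_ids=["a"], thresholds=[np.array([0.0])])
        pe = PersonEstimates(theta=np.array([0.0, 0.5]), se=np.ones(2),
                             raw_score=np.array([0, 1]),
                             extreme=np.array([False, False]), method="wle")
        prof = reliability_profile(ip, pe, psi_threshold=0.7)
        assert prof.intervals == []
        assert prof.pct_inside == 0.0

    def test_adding_an_item_never_decreases_information(self, uni_fit):
        _, _, res = uni_fit
        grid = np.linspace(-5, 5, 41)
        small = res.test_information(grid, items=res.params.item_ids[:7])
        large = res.test_information(grid, items=res.params.item_ids[:8])
        assert np.all(large >= small)

    def test_coverage_matches_long_run_oracle(self):
        # independent oracle: integrate the raw-score distribution over the
        # generating person density and push scores through their WLE
        # locations; the sample coverage must sit within Monte-Carlo error
        ths = {f"i{j}": np.array([-1.2, -0.4, 0.4, 1.2]) + mu
               for j, mu in enumerate(np.linspace(-0.6, 1.6, 7))}
        spec = SimulationSpec(n_persons=2000, thresholds=ths, person_mean=0.9,
                              person_sd=1.6, seed=81)
        rm, truth = simulate_pcm(spec)
        res = PartialCreditModel(rm).fit(compute_se=False)
        pe = res.person_estimates()
        prof = res.reliability(0.7, pe)
        a, b = prof.intervals[0]

        # long-run coverage: P(raw score r | theta) from the GENERATING
        # thresholds, theta ~ N(0.9, 1.6^2); r located by the FITTED table
        tbl = res.score_table().table
        inside_scores = tbl.index[(tbl["theta"] >= a) & (tbl["theta"] <= b)]
        grid = np.linspace(0.9 - 8 * 1.6, 0.9 + 8 * 1.6, 801)
        dens = np.exp(-0.5 * ((grid - 0.9) / 1.6) ** 2) / (1.6 * np.sqrt(2 * np.pi))
        score_dist = np.zeros((grid.size, 29))
        acc = np.ones((grid.size, 1))
        for t in ths.values():
            p = category_probability(grid, t)
            new = np.zeros((grid.size, acc.shape[1] + 4))
            for x in range(5):
                new[:, x: x + acc.shape[1]] += acc * p[:, [x]]
            acc = new
        score_dist = acc
        p_inside = score_dist[:, list(inside_scores)].sum(axis=1)
        longrun = 100.0 * np.trapezoid(p_inside * dens, grid)
        assert prof.pct_inside == pytest.approx(longrun, abs=2.5)
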