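"""Partial credit model: closed form, calibration, and person measurement."""

import numpy as np
import pandas as pd
import pytest

from mdsmetrics import (
    ItemParams,
    category_probabilities,
    estimate_abilities,
    fit_pcm,
    simulate_survey,
    GeneratingSpec,
)
from mdsmetrics.synth import default_item_bank


def brute_force_pcm(theta, steps):
    """Independent oracle: explicit loop over cumulative sums."""
    m = len(steps)
    num = []
    for x in range(m + 1):
        s = 0.0
        for k in range(x):
            s += theta - steps[k]
        num.append(np.exp(s))
    total = sum(num)
    return np.array([v / total for v in num])


def random_item(rng, m=None):
    m = m or rng.integers(1, 6)
    return ItemParams.from_steps("it", rng.normal(0.0, 1.5, size=m))


class TestCategoryProbabilities:
    def test_matches_brute_force_cumulative_sums(self):
        rng = np.random.default_rng(12345)
        for _ in range(300):
            item = random_item(rng)
            theta = rng.normal(0.0, 2.0)
            p = category_probabilities(theta, item)
            expected = brute_force_pcm(theta, item.steps)
            assert np.max(np.abs(p - expected)) < 1e-12
            assert abs(p.sum() - 1.0) < 1e-12
            assert np.all(p > 0) and np.all(p < 1)

    def test_dichotomous_threshold_is_equiprobability_point(self):
        item = ItemParams(name="d", difficulty=0.7, thresholds=np.array([0.0]))
        p = category_probabilities(item.difficulty + item.thresholds[0], item)
        assert np.allclose(p, [0.5, 0.5], atol=1e-12)

    def test_adjacent_categories_equal_at_each_threshold(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            item = random_item(rng)
            for k in range(item.n_categories - 1):
                p = category_probabilities(item.steps[k], item)
                assert abs(p[k] - p[k + 1]) < 1e-10

    def test_three_category_hand_example(self):
        # delta=0, tau=(-1, 1), theta=0: probabilities proportional to (1, e, 1)
        item = ItemParams(name="h", difficulty=0.0, thresholds=np.array([-1.0, 1.0]))
        p = category_probabilities(0.0, item)
        e = np.e
        expected = np.array([1.0, e, 1.0]) / (2.0 + e)
        assert np.allclose(p, expected, atol=1e-14)

    def test_nonfinite_theta_rejected(self):
        item = ItemParams(name="x", difficulty=0.0, thresholds=np.array([0.0]))
        with pytest.raises(ValueError):
            category_probabilities(np.nan, item)

    def test_location_shift_invariance(self):
        # adding c to both person ability and item location leaves
        # probabilities unchanged
        rng = np.random.default_rng(3)
        for _ in range(20):
            item = random_item(rng)
            c = rng.normal()
            shifted = ItemParams(
                name="s", difficulty=item.difficulty + c, thresholds=item.thresholds
            )
            th = rng.normal()
            assert np.allclose(
                category_probabilities(th, item),
                category_probabilities(th + c, shifted),
                atol=1e-12,
            )


class TestFitPCM:
    def test_sum_zero_identification(self, capacity_fit):
        deltas = [it.difficulty for it in capacity_fit.items]
        assert abs(np.mean(deltas)) < 1e-8

    def test_converged_with_report(self, capacity_fit):
        rep = capacity_fit.report
        assert rep.converged
        assert rep.n_iterations >= 1
        assert np.isfinite(rep.final_gradient_norm)

    def test_loglik_nondecreasing(self, capacity_fit):
        tr = np.asarray(capacity_fit.report.loglik_trace)
        assert np.all(np.diff(tr) > -1e-6)

    def test_parameter_recovery(self, default_spec, dataset, capacity_fit):
        true_d = np.array([it.difficulty for it in default_spec.items])
        est_d = np.array(
            [capacity_fit.item(it.name).difficulty for it in default_spec.items]
        )
        assert np.corrcoef(true_d, est_d)[0, 1] > 0.99
        assert np.sqrt(np.mean((true_d - est_d) ** 2)) < 0.10

    def test_identical_items_get_identical_calibrations(self):
        ds = simulate_survey(GeneratingSpec(n_persons=500, seed=9, missing_rate=0.0))
        data = ds.capacity_responses[["item05", "item08"]].copy()
        data["clone"] = data["item05"]
        fit = fit_pcm(data)
        a, b = fit.item("item05"), fit.item("clone")
        assert abs(a.difficulty - b.difficulty) < 1e-6
        assert np.allclose(a.thresholds, b.thresholds, atol=1e-6)

    def test_reverse_coded_item_still_converges(self):
        ds = simulate_survey(GeneratingSpec(n_persons=800, seed=4, missing_rate=0.0))
        data = ds.capacity_responses.copy()
        data["item08"] = 4.0 - data["item08"]
        fit = fit_pcm(data)
        assert fit.report.converged

    def test_single_category_item_excluded_with_warning(self):
        ds = simulate_survey(GeneratingSpec(n_persons=300, seed=2, missing_rate=0.0))
        data = ds.capacity_responses.copy()
        data["constant"] = 1.0
        fit = fit_pcm(data)
        assert "constant" not in [it.name for it in fit.items]
        assert any("constant" in w for w in fit.report.warnings)

    def test_null_category_collapsed_with_map(self):
        rng = np.random.default_rng(0)
        theta = rng.normal(0, 1, 600)
        ds = simulate_survey(GeneratingSpec(n_persons=600, seed=5, missing_rate=0.0))
        data = ds.capacity_responses.copy()
        # relabel category 2 of one item to 3, leaving 2 unobserved
        col = data["item08"].to_numpy()
        col[col == 2.0] = 3.0
        data["item08"] = col
        fit = fit_pcm(data)
        it = fit.item("item08")
        assert it.n_categories == 4
        assert it.category_map == {0: 0, 1: 1, 3: 2, 4: 3}

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            fit_pcm(pd.DataFrame({"only": [0, 1, 1, 0]}))


class TestEstimateAbilities:
    def test_symmetric_bank_half_score_maps_to_zero(self):
        items = [
            ItemParams(name=f"i{j}", difficulty=0.0, thresholds=np.array([-1.0, 1.0]))
            for j in range(4)
        ]
        data = pd.DataFrame([[1, 1, 1, 1]], columns=[f"i{j}" for j in range(4)], dtype=float)
        est = estimate_abilities(data, items)
        assert abs(est["theta"].iloc[0]) < 1e-8

    def test_extreme_scores_finite_and_ordered(self, dataset, capacity_fit, capacity_persons):
        est = capacity_persons
        assert np.all(np.isfinite(est["theta"]))
        assert np.all(np.isfinite(est["se"]))
        zero = est.loc[(est["raw_score"] == 0)]
        if len(zero):
            nonextreme_min = est.loc[~est["extreme"], "theta"].min()
            assert np.all(zero["theta"] < nonextreme_min)

    def test_theta_monotone_in_raw_score_complete_data(self):
        items = default_item_bank(n_items=5, n_categories=3)
        cols = [it.name for it in items]
        max_score = 10
        rows = []
        for r in range(max_score + 1):
            codes = np.zeros(5)
            rem = r
            for j in range(5):
                take = min(2, rem)
                codes[j] = take
                rem -= take
            rows.append(codes)
        data = pd.DataFrame(rows, columns=cols, dtype=float)
        est = estimate_abilities(data, items)
        # data index order == raw score order by construction
        theta_by_score = est["theta"].to_numpy()
        assert np.all(np.diff(theta_by_score) > 0)

    def test_equal_raw_scores_equal_theta(self):
        # raw-score sufficiency on a common complete item set
        items = default_item_bank(n_items=4, n_categories=3)
        cols = [it.name for it in items]
        data = pd.DataFrame(
            [[2, 0, 1, 0], [0, 1, 0, 2], [1, 1, 1, 0]], columns=cols, dtype=float
        )
        est = estimate_abilities(data, items)
        assert est["theta"].iloc[0] == pytest.approx(est["theta"].iloc[1], abs=1e-10)
        assert est["theta"].iloc[2] == pytest.approx(est["theta"].iloc[0], abs=1e-10)

    def test_all_missing_person_excluded(self):
        items = default_item_bank(n_items=3, n_categories=3)
        cols = [it.name for it in items]
        data = pd.DataFrame(
            [[1, 1, 1], [np.nan, np.nan, np.nan]], columns=cols,
            index=["a", "b"], dtype=float,
        )
        est = estimate_abilities(data, items)
        assert list(est.index) == ["a"]

    def test_recovery_of_true_abilities(self, dataset, capacity_persons):
        truth = dataset.true_abilities.loc[capacity_persons.index, "theta_capacity"]
        r = np.corrcoef(capacity_persons["theta"], truth)[0, 1]
        assert r > 0.9
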