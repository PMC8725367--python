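"""Reliability, targeting, item fit, local dependence, dimensionality, DIF."""

import numpy as np
import pandas as pd
import pytest

from mdsmetrics import (
    GeneratingSpec,
    centering_judgment,
    compute_psi,
    dif_analysis,
    dimensionality,
    estimate_abilities,
    fit_pcm,
    item_fit,
    local_dependence,
    simulate_survey,
    targeting_summary,
)
from mdsmetrics.diagnostics import diagnose_scale
from mdsmetrics.pcm import residual_moments


def persons_frame(theta, se):
    return pd.DataFrame({"theta": theta, "se": se})


class TestPSI:
    def test_zero_error_gives_one(self):
        assert compute_psi(persons_frame([-1.0, 0.0, 1.0], [0.0, 0.0, 0.0])) == 1.0

    def test_error_dominates_floor_at_zero(self):
        assert compute_psi(persons_frame([-0.1, 0.0, 0.1], [5.0, 5.0, 5.0])) == 0.0

    def test_hand_evaluated_value(self):
        # theta (-2,-1,0,1,2): Var = 2.5 (n-1 divisor); se=1 -> (2.5-1)/2.5
        psi = compute_psi(persons_frame([-2.0, -1.0, 0.0, 1.0, 2.0], [1.0] * 5))
        assert psi == pytest.approx(0.6, abs=1e-12)

    def test_invariant_under_ability_shift(self, capacity_persons):
        shifted = capacity_persons.copy()
        shifted["theta"] = shifted["theta"] + 3.7
        assert compute_psi(shifted) == pytest.approx(
            compute_psi(capacity_persons), abs=1e-12
        )

    def test_converges_to_analytic_generating_reliability(self):
        spec = GeneratingSpec(n_persons=5000, seed=1, missing_rate=0.0)
        ds = simulate_survey(spec)
        fit = fit_pcm(ds.capacity_responses)
        pers = estimate_abilities(ds.capacity_responses, fit.items)
        psi = compute_psi(pers)
        theta = ds.true_abilities["theta_capacity"].to_numpy()
        _, V, _, _ = residual_moments(theta, list(spec.items))
        analytic = spec.ability_sd**2 / (
            spec.ability_sd**2 + (1.0 / V.sum(axis=1)).mean()
        )
        assert abs(psi - analytic) < 0.03


class TestTargeting:
    def test_printed_mean_006_judged_centered(self):
        assert centering_judgment(0.06).well_targeted

    def test_printed_mean_058_judged_not_centered(self):
        assert not centering_judgment(0.58).well_targeted

    def test_perfect_match_offset_zero(self, capacity_fit):
        persons = persons_frame([0.0, 0.0], [0.3, 0.3])
        summary, judgment = targeting_summary(capacity_fit.items, persons)
        assert judgment.centering_offset == pytest.approx(0.0, abs=1e-8)
        assert judgment.well_targeted

    def test_calibrated_bank_reports_zero_mean_difficulty(
        self, capacity_fit, capacity_persons
    ):
        summary, _ = targeting_summary(capacity_fit.items, capacity_persons)
        assert abs(summary["mean_item_difficulty"]) < 1e-6
        lo, hi = summary["threshold_range"]
        assert lo <= hi

    def test_empty_inputs_rejected(self, capacity_fit):
        with pytest.raises(ValueError):
            targeting_summary([], persons_frame([0.0], [0.1]))


class TestItemFit:
    def test_null_flag_rate_near_nominal(self, clean_dataset, clean_fit, clean_persons):
        fit = item_fit(clean_dataset.capacity_responses, clean_fit.items, clean_persons)
        # |z| > 2.5 flags ~1.2% of items under the null; 15 items -> expect 0,
        # allow up to 2 before calling the calibration off
        assert int(fit["misfit"].sum()) <= 2

    def test_unrelated_random_item_flagged_underfitting(self, clean_dataset):
        data = clean_dataset.capacity_responses.copy()
        rng = np.random.default_rng(5)
        data["noise_item"] = rng.integers(0, 5, len(data)).astype(float)
        fit = fit_pcm(data)
        pers = estimate_abilities(data, fit.items)
        stats = item_fit(data, fit.items, pers)
        assert bool(stats.loc["noise_item", "misfit"])
        assert stats.loc["noise_item", "fit_residual"] > 2.5  # underfit side

    def test_guttman_item_flagged_overfitting(self, clean_dataset):
        data = clean_dataset.capacity_responses.copy()
        theta = clean_dataset.true_abilities["theta_capacity"].to_numpy()
        cuts = np.quantile(theta, [0.2, 0.4, 0.6, 0.8])
        data["guttman_item"] = (theta[:, None] > cuts[None, :]).sum(axis=1).astype(float)
        fit = fit_pcm(data)
        pers = estimate_abilities(data, fit.items)
        stats = item_fit(data, fit.items, pers)
        assert bool(stats.loc["guttman_item", "misfit"])
        assert stats.loc["guttman_item", "fit_residual"] < -2.5  # deterministic

    def test_low_information_warning_flag(self, clean_fit):
        data = pd.DataFrame(
            {it.name: np.tile([0.0, 1.0, 2.0, 3.0, 4.0], 2) for it in clean_fit.items}
        )
        pers = estimate_abilities(data, clean_fit.items)
        stats = item_fit(data, clean_fit.items, pers)
        assert stats["low_information"].all()


class TestLocalDependence:
    def test_duplicated_item_pair_flagged_at_matrix_maximum(self, clean_dataset):
        data = clean_dataset.capacity_responses.copy()
        data["item07_dup"] = data["item07"]
        fit = fit_pcm(data)
        pers = estimate_abilities(data, fit.items)
        corr, flagged = local_dependence(data, fit.items, pers)
        pair_names = {frozenset(p[:2]) for p in flagged}
        assert frozenset(("item07", "item07_dup")) in pair_names
        vals = corr.to_numpy(copy=True)
        np.fill_diagonal(vals, -np.inf)
        assert corr.loc["item07", "item07_dup"] == pytest.approx(np.max(vals))

    def test_independent_items_no_systematic_flags(
        self, clean_dataset, clean_fit, clean_persons
    ):
        _, flagged = local_dependence(
            clean_dataset.capacity_responses, clean_fit.items, clean_persons
        )
        assert len(flagged) <= 1  # chance-level at most

    def test_single_item_empty_matrix(self, clean_fit, clean_persons, clean_dataset):
        corr, flagged = local_dependence(
            clean_dataset.capacity_responses, clean_fit.items[:1], clean_persons
        )
        assert corr.empty or corr.isna().all().all()
        assert flagged == []


class TestDimensionality:
    def test_unidimensional_simulation_accepted(
        self, clean_dataset, clean_fit, clean_persons
    ):
        res = dimensionality(
            clean_dataset.capacity_responses, clean_fit.items, clean_persons
        )
        assert res["test_performed"]
        assert res["unidimensional"] is True

    def test_two_factor_simulation_rejected(self, clean_dataset):
        # items 1-8 driven by one latent, 9-15 by a weakly correlated second
        from mdsmetrics.synth import _draw_responses, default_item_bank

        n = len(clean_dataset.capacity_responses)
        thA = clean_dataset.true_abilities["theta_capacity"].to_numpy()
        rng = np.random.default_rng(12)
        zA = (thA + 1.0) / 1.2
        thB = -1.0 + 1.2 * (0.3 * zA + np.sqrt(1 - 0.09) * rng.normal(size=n))
        bank = default_item_bank()
        respB = _draw_responses(np.random.default_rng(13), thB, bank[8:], 0.0)
        respB.index = clean_dataset.capacity_responses.index
        mixed = pd.concat(
            [clean_dataset.capacity_responses[[b.name for b in bank[:8]]], respB],
            axis=1,
        )
        fit = fit_pcm(mixed)
        pers = estimate_abilities(mixed, fit.items)
        res = dimensionality(mixed, fit.items, pers)
        assert res["test_performed"]
        assert res["unidimensional"] is False

    def test_too_few_items_per_subset_skipped(self, clean_dataset, clean_fit):
        few = clean_fit.items[:4]
        pers = estimate_abilities(clean_dataset.capacity_responses, few)
        res = dimensionality(clean_dataset.capacity_responses, few, pers)
        assert res["test_performed"] is False
        assert res["unidimensional"] is None


class TestDIF:
    @staticmethod
    def dif_dataset(seed, shift, n=2000, item_idx=7):
        from mdsmetrics.pcm import ItemParams
        from mdsmetrics.synth import default_item_bank

        bank = default_item_bank()
        shifted = tuple(
            ItemParams(
                it.name,
                it.difficulty + (shift if j == item_idx else 0.0),
                it.thresholds.copy(),
            )
            for j, it in enumerate(bank)
        )
        dA = simulate_survey(GeneratingSpec(n_persons=n // 2, seed=seed * 2 + 1, missing_rate=0.0))
        dB = simulate_survey(
            GeneratingSpec(n_persons=n // 2, items=shifted, seed=seed * 2 + 2, missing_rate=0.0)
        )
        b = dB.capacity_responses.copy()
        b.index = pd.Index([f"B{i:06d}" for i in range(n // 2)], name="person")
        data = pd.concat([dA.capacity_responses, b])
        groups = pd.DataFrame(
            {"grp": ["A"] * (n // 2) + ["B"] * (n // 2)}, index=data.index
        )
        return data, groups

    def test_planted_uniform_shift_detected(self):
        data, groups = self.dif_dataset(seed=0, shift=0.5)
        fit = fit_pcm(data)
        pers = estimate_abilities(data, fit.items)
        res = dif_analysis(data, fit.items, pers, groups)
        planted = res[(res["item"] == "item08")]
        assert bool(planted["uniform_dif"].iloc[0])

    def test_single_level_factor_rejected(self, clean_dataset, clean_fit, clean_persons):
        groups = pd.DataFrame(
            {"grp": ["only"] * len(clean_persons)}, index=clean_persons.index
        )
        with pytest.raises(ValueError):
            dif_analysis(
                clean_dataset.capacity_responses,
                clean_fit.items,
                clean_persons,
                groups,
            )


def test_full_report_bundles_all_sections(dataset, capacity_fit, capacity_persons):
    report = diagnose_scale(
        dataset.capacity_responses,
        capacity_fit.items,
        capacity_persons,
        factors=dataset.covariates[["sex"]],
    )
    d = report.to_dict()
    assert 0.0 <= d["psi"] <= 1.0
    assert "well_targeted" in d["targeting"]
    assert len(d["item_fit"]) == len(capacity_fit.items)
    assert d["dif"] is not None
    assert "settings" in d
    assert isinstance(report.summary(), str) and "PSI" in report.summary()
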