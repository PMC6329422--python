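"""Rasch engine: probability model, estimation, and model comparison."""

import numpy as np
import pandas as pd
import pytest

import ctclqol as cq
from ctclqol.errors import ComparisonError
from ctclqol.instrument import Instrument, Item, ResponseMatrix
from ctclqol.rasch import GRSMParams, ModelKind, item_variance

from test_simulate import brute_force_probs
from conftest import min_interference_row


TAU = np.array([-2.0, -1.0, 1.0, 2.0])


class TestCategoryProbs:
    def test_probabilities_normalize(self):
        p = cq.category_probs(0.3, -0.7, TAU)
        assert (p >= 0).all()
        assert abs(p.sum() - 1.0) < 1e-12

    def test_extreme_person_saturates_top_category(self):
        p = cq.category_probs(10.0, 0.0, np.zeros(4))
        assert p[-1] > 0.999

    def test_matches_brute_force_evaluation(self):
        p = cq.category_probs(0.0, 0.0, TAU)
        oracle = brute_force_probs(0.0, 0.0, TAU)
        assert np.abs(p - oracle).max() < 1e-10

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            cq.category_probs(np.nan, 0.0, TAU)
        with pytest.raises(ValueError):
            cq.category_probs(0.0, 0.0, [np.inf, 0, 0, 0])


class TestExpectedScoreAndVariance:
    def test_symmetric_thresholds_give_midpoint_at_theta_equals_delta(self):
        assert abs(cq.expected_score(0.5, 0.5, TAU) - 2.0) < 1e-12

    def test_variance_is_second_central_moment(self):
        p = cq.category_probs(0.4, -0.2, TAU)
        k = np.arange(5.0)
        direct = p @ k**2 - (p @ k) ** 2
        assert abs(item_variance(0.4, -0.2, TAU) - direct) < 1e-12

    @pytest.mark.parametrize("theta", [-2.0, -0.5, 0.0, 0.9, 2.5])
    def test_derivative_of_expected_score_is_the_variance(self, theta):
        h = 1e-6
        num = (
            cq.expected_score(theta + h, 0.3, TAU)
            - cq.expected_score(theta - h, 0.3, TAU)
        ) / (2 * h)
        assert abs(num - item_variance(theta, 0.3, TAU)) < 1e-6

    def test_expected_score_strictly_increasing(self):
        grid = np.linspace(-6, 6, 121)
        es = [cq.expected_score(t, 0.0, TAU) for t in grid]
        assert np.all(np.diff(es) > 0)


class TestFit:
    def test_difficulty_recovery_at_n_1000(self, instrument, sim1000, calib1000):
        truth = sim1000["truth"]
        rmse_delta = np.sqrt(
            np.mean((calib1000.params.delta - truth.delta) ** 2)
        )
        assert rmse_delta <= 0.15

    def test_threshold_recovery_at_n_1000(self, instrument):
        """Thresholds of moderate magnitude are recovered within 0.2 logits.

        Joint ML carries a small multiplicative scale expansion that grows
        with threshold magnitude, so this check uses a typical +/-1.8 span.
        """
        tau0 = np.array([-1.8, -0.6, 0.6, 1.8])
        truth = cq.make_truth(
            instrument, seed=20261,
            tau={"frequency": tau0.copy(), "intensity": tau0.copy()},
        )
        rm, _, _ = cq.simulate_responses(
            instrument, 1000, truth, with_covariates=False
        )
        res = cq.fit(rm, instrument)
        tau_err = np.concatenate(
            [res.params.tau[g] - truth.tau[g] for g in truth.tau]
        )
        assert np.sqrt(np.mean(tau_err**2)) <= 0.20

    def test_converges_and_respects_identification(self, calib1000):
        assert calib1000.converged
        assert abs(calib1000.params.delta.mean()) < 1e-8
        for t in calib1000.params.tau.values():
            assert abs(t.sum()) < 1e-6

    def test_extreme_person_excluded_but_measured(self, instrument):
        truth = cq.make_truth(instrument, seed=61)
        rm, _, _ = cq.simulate_responses(
            instrument, 150, truth, with_covariates=False
        )
        row = pd.Series(min_interference_row(instrument), dtype=float)
        rm.values.loc["extreme"] = row[rm.values.columns]
        res = cq.fit(rm, instrument)
        assert "extreme" in res.excluded_extreme_persons
        th = res.theta.loc["extreme"]
        assert np.isfinite(th)
        assert th < res.theta.drop("extreme").min()

    def test_grouped_fit_on_common_threshold_data(self, instrument):
        """Fitting free group thresholds to common-threshold data recovers
        equal thresholds within joint uncertainty."""
        tau0 = np.array([-2.0, -0.7, 0.7, 2.0])
        truth = cq.make_truth(
            instrument, seed=62,
            tau={"frequency": tau0.copy(), "intensity": tau0.copy()},
        )
        rm, _, _ = cq.simulate_responses(
            instrument, 1000, truth, with_covariates=False
        )
        res = cq.fit(rm, instrument, "grsm")
        tf, ti = res.params.tau["frequency"], res.params.tau["intensity"]
        sf, si = res.params.tau_se["frequency"], res.params.tau_se["intensity"]
        joint = np.sqrt(sf**2 + si**2)
        assert np.all(np.abs(tf - ti) <= 2.0 * joint)

    def test_equal_raw_totals_get_equal_measures(self, instrument):
        truth = cq.make_truth(instrument, seed=63)
        rm, _, _ = cq.simulate_responses(
            instrument, 300, truth, with_covariates=False
        )
        res = cq.fit(rm, instrument)
        scored = rm.scored(instrument)
        totals = scored.sum(axis=1)
        theta = res.theta
        for _, grp in theta.groupby(totals):
            if len(grp) > 1:
                assert grp.max() - grp.min() < 1e-5

    def test_bias_shrinks_with_sample_size(self, instrument):
        biases = {}
        for n in (200, 2000):
            vals = []
            for s in range(3):
                truth = cq.make_truth(instrument, seed=70 + s)
                rm, _, _ = cq.simulate_responses(
                    instrument, n, truth, with_covariates=False
                )
                res = cq.fit(rm, instrument)
                vals.append(np.mean(np.abs(res.params.delta - truth.delta)))
            biases[n] = np.mean(vals)
        assert biases[2000] < biases[200]


class TestModelComparison:
    def test_grouped_model_never_fits_worse(self, instrument):
        truth = cq.make_truth(instrument, seed=80)
        rm, _, _ = cq.simulate_responses(
            instrument, 400, truth, with_covariates=False
        )
        grsm = cq.fit(rm, instrument, "grsm")
        rsm = cq.fit(rm, instrument, "rsm")
        assert grsm.loglik >= rsm.loglik - 1e-6

    def test_lrt_df_is_3_for_two_groups_five_categories(
        self, instrument, sim1000
    ):
        rm = sim1000["responses"]
        grsm = cq.fit(rm, instrument, "grsm")
        rsm = cq.fit(rm, instrument, "rsm")
        out = cq.lrt_grsm_vs_rsm(grsm, rsm)
        assert out["df"] == 3
        assert out["chi2"] >= 0
        assert 0 <= out["p"] <= 1

    def test_single_group_makes_the_models_coincide(self):
        items = tuple(
            Item(id=f"i{j}", text="t", scale_group="intensity")
            for j in range(6)
        )
        inst = Instrument(items=items)
        truth = cq.SimulationTruth(
            delta=np.linspace(-1, 1, 6),
            tau={"intensity": np.array([-2.0, -1.0, 1.0, 2.0])},
            seed=81,
        )
        rm, _, _ = cq.simulate_responses(inst, 300, truth, with_covariates=False)
        grsm = cq.fit(rm, inst, "grsm")
        rsm = cq.fit(rm, inst, "rsm")
        out = cq.lrt_grsm_vs_rsm(grsm, rsm)
        assert out["df"] == 0
        assert out["chi2"] < 1e-3
        assert out["p"] == 1.0

    def test_mismatched_data_is_a_comparison_error(self, instrument):
        truth = cq.make_truth(instrument, seed=82)
        rm1, _, _ = cq.simulate_responses(instrument, 100, truth, with_covariates=False)
        truth2 = cq.make_truth(instrument, seed=83)
        rm2, _, _ = cq.simulate_responses(instrument, 100, truth2, with_covariates=False)
        grsm = cq.fit(rm1, instrument, "grsm")
        rsm = cq.fit(rm2, instrument, "rsm")
        with pytest.raises(ComparisonError):
            cq.lrt_grsm_vs_rsm(grsm, rsm)


class TestIccOverlay:
    def _pcm(self, instrument, seed=85, n=400):
        truth = cq.make_truth(instrument, seed=seed)
        rm, _, _ = cq.simulate_responses(instrument, n, truth, with_covariates=False)
        return cq.fit(rm, instrument, "pcm"), truth

    def test_identical_parameters_give_zero_dissimilarity(self, instrument):
        pcm, _ = self._pcm(instrument)
        # impose identical item parameters on two items, then re-measure
        p = pcm.params
        p.delta[1] = p.delta[0]
        p.tau[p.item_ids[1]] = p.tau[p.item_ids[0]].copy()
        overlay = cq.icc_overlay(pcm, instrument)
        a, b = p.item_ids[0], p.item_ids[1]
        assert np.abs(overlay["curves"][a] - overlay["curves"][b]).max() < 1e-12

    def test_curves_monotone_in_theta(self, instrument):
        pcm, _ = self._pcm(instrument)
        overlay = cq.icc_overlay(pcm, instrument)
        for c in overlay["curves"].values():
            assert np.all(np.diff(c) > -1e-12)

    def test_distinct_group_thresholds_separate_between_groups(self, instrument):
        truth = cq.make_truth(
            instrument,
            seed=86,
            tau={
                "frequency": np.array([-3.0, -1.0, 1.0, 3.0]),
                "intensity": np.array([-1.2, -0.4, 0.4, 1.2]),
            },
            delta=np.zeros(12),
        )
        rm, _, _ = cq.simulate_responses(instrument, 1500, truth, with_covariates=False)
        pcm = cq.fit(rm, instrument, "pcm")
        overlay = cq.icc_overlay(pcm, instrument)
        within = max(overlay["within_group_dissimilarity"].values())
        assert overlay["between_group_dissimilarity"] > within
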