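"""Fit statistics, purging, dimensionality, rating-scale and DIF diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import ctclqol as cq
from ctclqol.diagnostics import MISFIT_CUTOFF
from ctclqol.errors import InsufficientDataError
from ctclqol.instrument import Instrument, Item, ResponseMatrix
from ctclqol.rasch import (
    CalibrationResult,
    GRSMParams,
    ModelKind,
    item_variance,
)

from test_simulate import brute_force_probs


def toy_calibration():
    """A tiny hand-specified calibration (3 persons x 2 items, known params)."""
    items = (
        Item(id="a", text="a", scale_group="intensity"),
        Item(id="b", text="b", scale_group="intensity"),
    )
    inst = Instrument(items=items)
    tau = np.array([-1.5, -0.5, 0.5, 1.5])
    params = GRSMParams(
        model_kind=ModelKind.GRSM,
        person_ids=["p1", "p2", "p3"],
        item_ids=["a", "b"],
        theta=np.array([-1.0, 0.0, 1.2]),
        theta_se=np.full(3, 0.5),
        delta=np.array([-0.4, 0.4]),
        delta_se=np.full(2, 0.2),
        tau={"intensity": tau},
        tau_se={"intensity": np.full(4, 0.1)},
        item_group=["intensity", "intensity"],
    )
    values = pd.DataFrame(
        [[2, 1], [3, 3], [4, 5]],
        index=["p1", "p2", "p3"],
        columns=["a", "b"],
        dtype=float,
    )
    rm = ResponseMatrix(values=values)
    result = CalibrationResult(
        params=params,
        loglik=0.0,
        n_iter=1,
        converged=True,
        excluded_extreme_persons=[],
        excluded_extreme_items=[],
        residual_matrix=pd.DataFrame(),
        data_fingerprint="toy",
        tolerance=1e-4,
        instrument=inst,
    )
    return inst, rm, result, tau


class TestStandardizedResiduals:
    def test_matches_direct_recomputation(self):
        inst, rm, result, tau = toy_calibration()
        z = cq.standardized_residuals(result, rm, inst)
        k = np.arange(5.0)
        for pi, pid in enumerate(result.params.person_ids):
            for ii, iid in enumerate(result.params.item_ids):
                p = brute_force_probs(
                    result.params.theta[pi], result.params.delta[ii], tau
                )
                e = p @ k
                v = p @ k**2 - e**2
                x = rm.scored(inst).loc[pid, iid]
                assert abs(z.loc[pid, iid] - (x - e) / np.sqrt(v)) < 1e-10

    def test_cell_at_its_expectation_has_zero_residual(self):
        inst, rm, result, tau = toy_calibration()
        # symmetric thresholds, theta == delta => expectation exactly 2
        result.params.theta[1] = result.params.delta[0]
        rm.values.loc["p2", "a"] = 3.0  # category 2 on the 0-4 scale
        z = cq.standardized_residuals(result, rm, inst)
        assert abs(z.loc["p2", "a"]) < 1e-12

    def test_residual_mean_near_zero_under_the_model(
        self, instrument
    ):
        truth = cq.make_truth(instrument, seed=40)
        rm, _, _ = cq.simulate_responses(
            instrument, 2000, truth, with_covariates=False
        )
        res = cq.fit(rm, instrument)
        z = cq.standardized_residuals(res, rm, instrument)
        assert abs(np.nanmean(z.to_numpy())) < 0.02


class TestItemFit:
    def test_mean_squares_match_hand_computation(self):
        inst, rm, result, tau = toy_calibration()
        rep = cq.item_fit(result, rm, inst)
        k = np.arange(5.0)
        scored = rm.scored(inst)
        for ii, iid in enumerate(result.params.item_ids):
            z2s, vs, wz2 = [], [], []
            for pi, pid in enumerate(result.params.person_ids):
                p = brute_force_probs(
                    result.params.theta[pi], result.params.delta[ii], tau
                )
                e = p @ k
                v = p @ k**2 - e**2
                x = scored.loc[pid, iid]
                z2s.append((x - e) ** 2 / v)
                vs.append(v)
                wz2.append((x - e) ** 2)
            assert abs(rep.item.loc[iid, "outfit"] - np.mean(z2s)) < 1e-10
            assert (
                abs(rep.item.loc[iid, "infit"] - np.sum(wz2) / np.sum(vs))
                < 1e-10
            )

    def test_model_true_items_fit_within_conventional_bounds(
        self, instrument, sim1000, calib1000
    ):
        rep = cq.item_fit(calib1000, sim1000["responses"], instrument)
        assert (rep.item.infit.between(0.8, 1.2)).all()
        assert (rep.item.outfit.between(0.8, 1.2)).all()

    def test_outfit_grand_mean_near_one(self, instrument):
        truth = cq.make_truth(instrument, seed=41)
        rm, _, _ = cq.simulate_responses(
            instrument, 2000, truth, with_covariates=False
        )
        res = cq.fit(rm, instrument)
        rep = cq.item_fit(res, rm, instrument)
        assert abs(rep.item.outfit.mean() - 1.0) < 0.05

    def test_uniform_random_item_detected_by_outfit(self, instrument, bank):
        """A single off-model item exceeds the misfit cutoff nearly always."""
        inst13 = bank.subset([f"q{i:02d}" for i in range(1, 14)])
        hits = 0
        n_reps = 200
        for rep_i in range(n_reps):
            truth = cq.make_truth(
                inst13, seed=50_000 + rep_i, misfit_items={"q13"}, dna_rate=0.0
            )
            rm, _, _ = cq.simulate_responses(
                inst13, 400, truth, with_covariates=False
            )
            res = cq.fit(rm, inst13)
            rep = cq.item_fit(res, rm, inst13)
            hits += rep.item.loc["q13", "outfit"] > MISFIT_CUTOFF
        assert hits / n_reps >= 0.95


class TestPurgeItems:
    def test_exactly_the_two_noise_items_are_removed(self, purge_result):
        assert sorted(purge_result["removed"]) == ["q08", "q13"]
        assert len(purge_result["retained"]) == 12

    def test_purge_is_idempotent(self, bank, purge_fixture, purge_result):
        inst = bank.subset(purge_result["retained"])
        again = cq.purge_items(purge_fixture["responses"], inst)
        assert again["removed"] == []

    def test_model_true_data_loses_nothing(self, instrument, sim1000):
        out = cq.purge_items(sim1000["responses"], instrument)
        assert out["removed"] == []

    def test_removal_order_is_deterministic(self, bank, purge_fixture, purge_result):
        again = cq.purge_items(purge_fixture["responses"], bank)
        assert again["removed"] == purge_result["removed"]
        assert again["log"] == purge_result["log"]


class TestPcaFirstContrast:
    def test_eigenvalues_sum_to_item_count(self, instrument, sim1000, calib1000):
        z = cq.standardized_residuals(calib1000, sim1000["responses"], instrument)
        out = cq.pca_first_contrast(z.dropna(how="any"))
        assert abs(out["eigenvalues"].sum() - 12) < 1e-8

    def test_unidimensional_data_stays_below_two(self, instrument):
        firsts = []
        for rep_i in range(60):
            truth = cq.make_truth(instrument, seed=60_000 + rep_i, dna_rate=0.0)
            rm, _, _ = cq.simulate_responses(
                instrument, 500, truth, with_covariates=False
            )
            res = cq.fit(rm, instrument)
            out = cq.dimensionality_report(res, rm, instrument)
            firsts.append(out["first_contrast_eigenvalue"])
        assert np.median(firsts) < 2.0

    def test_second_dimension_raises_first_contrast(self, instrument):
        """Six items driven by an orthogonal second factor (loading 0.8)."""
        hits = 0
        n_reps = 60
        rng = np.random.default_rng(123)
        for rep_i in range(n_reps):
            truth = cq.make_truth(instrument, seed=70_000 + rep_i, dna_rate=0.0)
            t1 = rng.standard_normal(500)
            t2 = rng.standard_normal(500)
            # first six items driven by factor 1; last six by a 0.6/0.8 mix
            rm, _, _ = cq.simulate_responses(
                instrument, 500, truth, with_covariates=False, theta=t1
            )
            vals = rm.values.to_numpy().copy()
            rm2, _, _ = cq.simulate_responses(
                instrument,
                500,
                cq.make_truth(instrument, seed=80_000 + rep_i, dna_rate=0.0),
                with_covariates=False,
                theta=0.6 * t1 + 0.8 * t2,
            )
            vals[:, 6:] = rm2.values.to_numpy()[:, 6:]
            rm_mixed = ResponseMatrix(
                values=pd.DataFrame(
                    vals, index=rm.values.index, columns=rm.values.columns
                )
            )
            res = cq.fit(rm_mixed, instrument)
            out = cq.dimensionality_report(res, rm_mixed, instrument)
            hits += out["first_contrast_eigenvalue"] > 2.0
        assert hits / n_reps >= 0.9

    def test_variance_explained_reported(self, instrument, sim1000, calib1000):
        out = cq.dimensionality_report(calib1000, sim1000["responses"], instrument)
        assert 0 < out["variance_explained_by_measures_pct"] < 100


class TestRatingScale:
    def test_ordered_and_disordered_thresholds_detected(self):
        inst, rm, result, tau = toy_calibration()
        assert cq.thresholds_ordered(result)["intensity"]["ordered"]
        result.params.tau["intensity"] = np.array([-1.0, -2.0, 1.0, 2.0])
        assert not cq.thresholds_ordered(result)["intensity"]["ordered"]

    def test_ordering_recovered_from_ordered_truth(self, instrument):
        hits = 0
        n_reps = 50
        for rep_i in range(n_reps):
            truth = cq.make_truth(instrument, seed=90_000 + rep_i, dna_rate=0.0)
            rm, _, _ = cq.simulate_responses(
                instrument, 1000, truth, with_covariates=False
            )
            res = cq.fit(rm, instrument)
            ordered = cq.thresholds_ordered(res)
            hits += all(d["ordered"] for d in ordered.values())
        assert hits / n_reps >= 0.95

    def test_curves_match_category_probs_and_sum_to_one(self):
        inst, rm, result, tau = toy_calibration()
        cc = cq.category_curves(result, "intensity")
        np.testing.assert_allclose(cc["probs"].sum(axis=1), 1.0, atol=1e-12)
        for gi, g in enumerate(cc["grid"]):
            np.testing.assert_allclose(
                cc["probs"][gi], cq.category_probs(g, 0.0, tau), atol=1e-12
            )

    def test_adjacent_curves_cross_at_the_thresholds(self):
        inst, rm, result, tau = toy_calibration()

        def crossing(k):
            f = lambda x: (
                cq.category_probs(x, 0.0, tau)[k]
                - cq.category_probs(x, 0.0, tau)[k + 1]
            )
            return optimize.brentq(f, -6, 6)

        for k in range(4):
            assert abs(crossing(k) - tau[k]) < 1e-9


class TestTestInformation:
    def test_single_item_information_matches_brute_force(self):
        inst, rm, result, tau = toy_calibration()
        result.params.delta = np.array([0.0, 0.0])
        ti = cq.test_information(result, np.array([0.0]))
        k = np.arange(5.0)
        p = brute_force_probs(0.0, 0.0, tau)
        per_item = p @ k**2 - (p @ k) ** 2
        assert abs(ti["information"][0] - 2 * per_item) < 1e-10

    def test_symmetric_configuration_gives_symmetric_curve(self):
        inst, rm, result, tau = toy_calibration()
        result.params.delta = np.zeros(2)
        grid = np.linspace(-4, 4, 81)
        ti = cq.test_information(result, grid)
        assert np.abs(ti["information"] - ti["information"][::-1]).max() < 1e-9

    def test_information_nonnegative_and_sem_consistent(self, calib1000):
        ti = cq.test_information(calib1000)
        assert (ti["information"] >= 0).all()
        np.testing.assert_allclose(
            ti["sem"], 1 / np.sqrt(ti["information"]), atol=1e-12
        )


class TestPersonItemMap:
    def test_items_ordered_by_difficulty(self, calib1000):
        m = cq.person_item_map(calib1000)
        assert m["items"].is_monotonic_increasing

    def test_serialization_round_trip(self, calib1000):
        from ctclqol.diagnostics import map_from_dict, map_to_dict

        m = cq.person_item_map(calib1000)
        back = map_from_dict(map_to_dict(m))
        np.testing.assert_allclose(
            back["persons"].to_numpy(), m["persons"].to_numpy()
        )
        assert back["targeting"] == m["targeting"]

    def test_downshifted_persons_flag_low_end_undercoverage(self, instrument):
        truth = cq.make_truth(instrument, seed=95, theta_mean=-0.5)
        rm, _, _ = cq.simulate_responses(
            instrument, 400, truth, with_covariates=False
        )
        res = cq.fit(rm, instrument)
        m = cq.person_item_map(res)
        assert m["targeting"]["undercoverage_low"]
        assert (
            m["targeting"]["frac_persons_below_items"]
            > m["targeting"]["frac_persons_above_items"]
        )


@pytest.fixture(scope="module")
def dif_data(instrument):
    truth = cq.make_truth(
        instrument,
        seed=97,
        dif_spec={"item": "q03", "covariate": "gender", "contrast": 1.5},
    )
    rm, _, _ = cq.simulate_responses(instrument, 600, truth)
    res = cq.fit(rm, instrument)
    return rm, res


class TestDif:
    def test_injected_contrast_detected_and_signed(self, dif_data):
        rm, res = dif_data
        rep = cq.dif(rm, res, rm.covariates["gender"])
        assert "q03" in rep.flagged_items
        row = rep.table.set_index("item").loc["q03"]
        assert abs(abs(row["contrast"]) - 1.5) < 0.5

    def test_contrast_antisymmetric_under_label_swap(self, dif_data):
        rm, res = dif_data
        rep = cq.dif(rm, res, rm.covariates["gender"])
        swapped = rm.covariates["gender"].map(
            {"female": "male", "male": "female"}
        )
        rep2 = cq.dif(rm, res, swapped)
        a = rep.table.set_index("item")["contrast"]
        b = rep2.table.set_index("item")["contrast"]
        np.testing.assert_allclose(a.to_numpy(), -b.to_numpy(), atol=1e-8)
        assert rep.flagged_items == rep2.flagged_items

    def test_flags_invariant_to_measure_translation(self, dif_data):
        import copy

        rm, res = dif_data
        rep = cq.dif(rm, res, rm.covariates["gender"])
        shifted = copy.deepcopy(res)
        shifted.params.theta = shifted.params.theta + 0.8
        rep2 = cq.dif(rm, shifted, rm.covariates["gender"])
        np.testing.assert_allclose(
            rep.table["contrast"].to_numpy(),
            rep2.table["contrast"].to_numpy(),
            atol=1e-6,
        )

    def test_too_small_groups_rejected(self, dif_data):
        rm, res = dif_data
        tiny = pd.Series("a", index=rm.values.index)
        tiny.iloc[:5] = "b"
        with pytest.raises(InsufficientDataError):
            cq.dif(rm, res, tiny)
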