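"""Normative model: split bookkeeping, recovery, calibration, invariances."""

import numpy as np
import pandas as pd
import pytest

from molnorm.react_core import RoiMatrix
from molnorm.normative_model import (
    deviation_scores,
    explained_variance,
    fit_hbr,
    retain_rois,
    stratified_split,
    summary_deviation,
)
from molnorm.synthetic_data import (
    SyntheticConfig,
    inject_deviations,
    make_cohort,
    make_ground_truth,
    simulate_roi_matrix,
)


def _healthy(site_sizes: dict[str, int]) -> pd.DataFrame:
    rows = []
    i = 0
    for site, n in site_sizes.items():
        for _ in range(n):
            rows.append({"id": f"s{i}", "site": site, "age": 40.0, "sex": 0,
                         "diagnosis": "HC"})
            i += 1
    return pd.DataFrame(rows)


class TestStratifiedSplit:
    def test_two_site_largest_remainder_bookkeeping(self):
        """A 496/111 healthy cohort at 70/30 gives 150/33 held-out subjects."""
        split = stratified_split(_healthy({"big": 496, "small": 111}), 0.30, seed=0)
        assert len(split.test_ids["big"]) == 150
        assert len(split.train_ids["big"]) == 346
        assert len(split.test_ids["small"]) == 33
        assert len(split.train_ids["small"]) == 78

    def test_single_site_ceiling(self):
        split = stratified_split(_healthy({"A": 10}), 0.30, seed=1)
        assert len(split.test_ids["A"]) == 3
        assert len(split.train_ids["A"]) == 7

    def test_partitions_disjoint_and_exhaustive(self):
        split = stratified_split(_healthy({"A": 37, "B": 23}), 0.30, seed=5)
        train, test = set(split.all_train()), set(split.all_test())
        assert not train & test
        assert len(train | test) == 60

    def test_seed_determinism(self):
        h = _healthy({"A": 30, "B": 30})
        a = stratified_split(h, 0.30, seed=9)
        b = stratified_split(h, 0.30, seed=9)
        assert a.test_ids == b.test_ids and a.train_ids == b.train_ids

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2])
    def test_invalid_fraction_rejected(self, frac):
        with pytest.raises(ValueError):
            stratified_split(_healthy({"A": 10}), frac, seed=0)


def _toy_cells(rng, n=200, sites=("A",), slope=2.0, noise=0.0, offsets=None):
    per = n // len(sites)
    cohort = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(per * len(sites))],
            "site": np.repeat(list(sites), per),
            "age": rng.uniform(18, 88, per * len(sites)),
            "sex": rng.integers(0, 2, per * len(sites)),
            "diagnosis": "HC",
        }
    )
    off = np.zeros(len(cohort))
    if offsets:
        off = cohort["site"].map(offsets).to_numpy()
    y = 1.0 + slope * cohort["age"].to_numpy() + off
    if noise:
        y = y + rng.normal(0, noise, len(y))
    rm = RoiMatrix(y.reshape(-1, 1, 1), {1: "r1"}, ["sysA"], list(cohort["id"]))
    return rm, cohort


@pytest.mark.parametrize("mode", ["eb", "gibbs"])
class TestParameterRecovery:
    def test_noiseless_slope_recovered(self, rng, mode):
        rm, cohort = _toy_cells(rng, n=200, slope=2.0, noise=0.0)
        fit = fit_hbr(rm, cohort, mode=mode, seed=3)
        assert fit.age_slope()[0, 0] == pytest.approx(2.0, abs=0.05)
        inter = fit.coef_mean[0, 0, 0]
        assert inter == pytest.approx(1.0, abs=0.5)

    def test_two_site_offsets_recovered(self, rng, mode):
        rm, cohort = _toy_cells(
            rng, n=400, sites=("A", "B"), slope=0.01, noise=0.5,
            offsets={"A": 0.5, "B": -0.5},
        )
        fit = fit_hbr(rm, cohort, mode=mode, seed=4)
        rec = fit.site_offsets()[0, 0]
        assert rec[0] == pytest.approx(0.5, abs=0.15)
        assert rec[1] == pytest.approx(-0.5, abs=0.15)


class TestGibbsCalibration:
    def test_null_slope_credible_interval_covers_zero(self, rng):
        """Pure-noise outcomes: the 95% CI on the age slope covers 0 most times."""
        covered = 0
        n_rep = 12
        for rep in range(n_rep):
            r = np.random.default_rng(100 + rep)
            cohort = pd.DataFrame(
                {
                    "id": [f"s{i}" for i in range(80)],
                    "site": "A",
                    "age": r.uniform(18, 88, 80),
                    "sex": r.integers(0, 2, 80),
                    "diagnosis": "HC",
                }
            )
            y = r.normal(0, 1, 80)
            rm = RoiMatrix(y.reshape(-1, 1, 1), {1: "r"}, ["s"], list(cohort["id"]))
            fit = fit_hbr(rm, cohort, mode="gibbs", seed=rep,
                          sampler_settings={"n_warmup": 400, "n_draws": 400})
            mean = fit.age_slope()[0, 0]
            sd = np.sqrt(fit.coef_cov[0, 0, -2, -2])
            covered += abs(mean) < 1.96 * sd
        assert covered >= int(0.75 * n_rep)


class TestExplainedVariance:
    def _fit_and_test(self, rng):
        rm, cohort = _toy_cells(rng, n=300, slope=0.02, noise=0.5)
        split = stratified_split(cohort, 0.3, seed=0)
        fit = fit_hbr(rm, cohort, train_ids=split.all_train(), mode="eb")
        idx = [rm.subject_ids.index(i) for i in split.all_test()]
        test = RoiMatrix(rm.values[idx], rm.roi_names, rm.system_names,
                         split.all_test())
        return fit, test, cohort

    def test_formula_matches_hand_computation(self, rng):
        """Arbitrary fixed predictions vs 1 - SSE/SST computed by hand."""
        rm, cohort = _toy_cells(rng, n=50, noise=0.5)
        fit = fit_hbr(rm, cohort, mode="eb")
        # freeze predictions: only the site intercept is nonzero, so every
        # subject is predicted the constant 2.5
        fit.coef_mean[:] = 0.0
        fit.coef_mean[0, 0, 0] = 2.5
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        sub = cohort.iloc[:5]
        test = RoiMatrix(y.reshape(-1, 1, 1), rm.roi_names, rm.system_names,
                         list(sub["id"]))
        ev = explained_variance(fit, test, cohort)
        sse = np.sum((y - 2.5) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        assert ev[0, 0] == pytest.approx(1 - sse / sst, abs=1e-12)

    def test_predicting_test_mean_gives_zero_ev(self, rng):
        rm, cohort = _toy_cells(rng, n=50, noise=0.5)
        fit = fit_hbr(rm, cohort, mode="eb")
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit.coef_mean[:] = 0.0
        fit.coef_mean[0, 0, 0] = y.mean()
        sub = cohort.iloc[:5]
        test = RoiMatrix(y.reshape(-1, 1, 1), rm.roi_names, rm.system_names,
                         list(sub["id"]))
        ev = explained_variance(fit, test, cohort)
        assert ev[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_predictions_give_unit_ev(self, rng):
        fit, test, cohort = self._fit_and_test(rng)
        exact = RoiMatrix(test.values.copy(), test.roi_names, test.system_names,
                          test.subject_ids)
        from molnorm.normative_model import predict

        mu, _ = predict(fit, cohort.set_index("id", drop=False).loc[test.subject_ids])
        exact.values[:] = mu
        ev = explained_variance(fit, exact, cohort)
        assert ev[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_test_variance_flagged_nan(self, rng):
        fit, test, cohort = self._fit_and_test(rng)
        test.values[:] = 7.0
        ev = explained_variance(fit, test, cohort)
        assert np.isnan(ev[0, 0])


class TestRetention:
    def _fit(self, rng, ev_values, converged):
        rm, cohort = _toy_cells(rng, n=50, noise=0.5)
        fit = fit_hbr(rm, cohort, mode="eb")
        k = len(ev_values)
        fit.ev = np.asarray(ev_values, dtype=float).reshape(1, k)
        fit.converged = np.asarray(converged, dtype=bool).reshape(1, k)
        return fit

    def test_strictly_positive_ev_required(self, rng):
        fit = self._fit(rng, [0.2, -0.1, 0.0], [True, True, True])
        assert retain_rois(fit).tolist() == [[True, False, False]]

    def test_nonconverged_cell_excluded_despite_positive_ev(self, rng):
        fit = self._fit(rng, [0.3, 0.3], [False, True])
        assert retain_rois(fit).tolist() == [[False, True]]

    def test_requires_ev(self, rng):
        rm, cohort = _toy_cells(rng, n=50, noise=0.5)
        fit = fit_hbr(rm, cohort, mode="eb")
        with pytest.raises(ValueError):
            retain_rois(fit)


@pytest.fixture(scope="module")
def calibration():
    cfg = SyntheticConfig(
        seed=21, n_systems=2, n_rois=10,
        n_subjects_per_site={"A": 300, "B": 300},
        n_patients_per_group={"G1": 100},
    )
    cohort = make_cohort(cfg)
    truth = make_ground_truth(cfg)
    rm = inject_deviations(simulate_roi_matrix(cohort, truth, cfg), cohort, truth)
    split = stratified_split(cohort, 0.3, seed=0)
    fit = fit_hbr(rm, cohort, train_ids=split.all_train(), mode="eb")
    idx = [rm.subject_ids.index(i) for i in split.all_test()]
    test = RoiMatrix(rm.values[idx], rm.roi_names, rm.system_names,
                     split.all_test())
    explained_variance(fit, test, cohort)
    return cfg, cohort, truth, rm, fit, test


class TestDeviationScores:
    def test_zero_residual_gives_zero_z(self, rng):
        rm, cohort = _toy_cells(rng, n=60, noise=0.5)
        fit = fit_hbr(rm, cohort, mode="eb")
        fit.ev = np.ones((1, 1))
        from molnorm.normative_model import predict

        mu, _ = predict(fit, cohort.set_index("id", drop=False).loc[rm.subject_ids])
        exact = RoiMatrix(mu, rm.roi_names, rm.system_names, rm.subject_ids)
        tensor = deviation_scores(fit, exact, cohort)
        assert np.allclose(tensor.z, 0.0, atol=1e-12)

    def test_held_out_healthy_scores_standard_normal(self, calibration):
        _, cohort, _, _, fit, test = calibration
        tensor = deviation_scores(fit, test, cohort)
        pooled = tensor.z[:, tensor.retained]
        assert abs(pooled.mean()) < 0.1
        assert 0.8 < pooled.var() < 1.2

    def test_planted_patient_shift_recovered(self, calibration):
        cfg, cohort, truth, rm, fit, _ = calibration
        pat = (cohort["diagnosis"] == "G1").to_numpy()
        ids = [i for i, p in zip(rm.subject_ids, pat) if p]
        idx = [rm.subject_ids.index(i) for i in ids]
        pm = RoiMatrix(rm.values[idx], rm.roi_names, rm.system_names, ids)
        tensor = deviation_scores(fit, pm, cohort)
        planted = truth.planted_deviation_map["G1"] != 0
        assert tensor.z[:, planted].mean() == pytest.approx(-1.0, abs=0.2)

    def test_unseen_site_raises(self, rng):
        rm, cohort = _toy_cells(rng, n=60, noise=0.5)
        fit = fit_hbr(rm, cohort, mode="eb")
        fit.ev = np.ones((1, 1))
        other = cohort.copy()
        other["site"] = "Z"
        with pytest.raises(ValueError):
            deviation_scores(fit, rm, other)

    def test_constant_shift_invariance(self, rng):
        """Adding c to all train and test y shifts predictions, not z."""
        rm, cohort = _toy_cells(rng, n=200, slope=0.01, noise=0.5)
        fit1 = fit_hbr(rm, cohort, mode="eb")
        fit1.ev = np.ones((1, 1))
        t1 = deviation_scores(fit1, rm, cohort)
        shifted = RoiMatrix(rm.values + 10.0, rm.roi_names, rm.system_names,
                            rm.subject_ids)
        fit2 = fit_hbr(shifted, cohort, mode="eb")
        fit2.ev = np.ones((1, 1))
        t2 = deviation_scores(fit2, shifted, cohort)
        assert np.allclose(t1.z, t2.z, atol=1e-8)


class TestSummaryDeviation:
    def _tensor(self, z, retained):
        from molnorm.normative_model import DeviationTensor

        n, r, k = z.shape
        return DeviationTensor(
            z=z, retained=retained,
            subject_ids=[f"s{i}" for i in range(n)],
            roi_names={i + 1: f"r{i}" for i in range(r)},
            system_names=[f"k{i}" for i in range(k)],
        )

    def test_simple_means(self):
        z = np.array([[[1.0], [-1.0]], [[2.0], [2.0]]])
        tensor = self._tensor(z, np.ones((2, 1), dtype=bool))
        out = summary_deviation(tensor)
        assert out.iloc[0, 0] == pytest.approx(0.0)
        assert out.iloc[1, 0] == pytest.approx(2.0)

    def test_matches_hand_computed_means_over_retained(self, rng):
        z = rng.standard_normal((3, 5, 2))
        retained = rng.random((5, 2)) > 0.4
        retained[0, :] = True  # keep both systems nonempty
        tensor = self._tensor(z, retained)
        out = summary_deviation(tensor)
        for i in range(3):
            for k in range(2):
                expect = z[i, retained[:, k], k].mean()
                assert out.iloc[i, k] == pytest.approx(expect, abs=1e-12)

    def test_empty_mask_yields_nan_with_warning(self, rng):
        z = rng.standard_normal((2, 3, 2))
        retained = np.ones((3, 2), dtype=bool)
        retained[:, 1] = False
        tensor = self._tensor(z, retained)
        with pytest.warns(UserWarning):
            out = summary_deviation(tensor)
        assert out.iloc[:, 1].isna().all()
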