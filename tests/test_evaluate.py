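"""Metrics, cross-validation harnesses, and concentration inversion."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import semiquant as sq
from semiquant.errors import ConfigurationError
from semiquant.evaluate import LN2, _hash_training_inputs


class TestAccuracyScore:
    def test_perfect_predictions(self):
        assert sq.accuracy_score([0.3, -2.0, 5.1], [0.3, -2.0, 5.1]) == 1.0

    def test_worked_example(self):
        assert sq.accuracy_score([0, 0, 0, 0], [0, 0.5, 0.8, 2.0], t=LN2) == 0.5

    def test_boundary_deviation_counts_incorrect(self):
        assert sq.accuracy_score([0.0, 0.0], [LN2, -LN2], t=LN2) == 0.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            sq.accuracy_score([1.0], [1.0, 2.0])

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=30),
        st.floats(-3, 3),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_shift_invariance_and_range(self, beta, shift):
        rng = np.random.default_rng(0)
        beta = np.asarray(beta)
        beta_hat = beta + rng.normal(0, 1, beta.size)
        a = sq.accuracy_score(beta_hat, beta)
        assert 0.0 <= a <= 1.0
        assert sq.accuracy_score(beta_hat + shift, beta + shift) == a
        assert a * beta.size == pytest.approx(round(a * beta.size))


class TestMaeMse:
    def test_hand_example(self):
        m = sq.mae_mse([1, 2], [0, 0])
        assert m.mae == pytest.approx(1.5)
        assert m.mse == pytest.approx(2.5)
        assert m.n == 2

    def test_exclusion_gives_mae_star(self):
        m = sq.mae_mse([0.1, -0.1, 10.0], [0.0, 0.0, 0.0], exclude=[2], ids=["a", "b", "c"])
        assert m.mae == pytest.approx(0.1)
        assert m.excluded_ids == ["c"]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        yh, y = rng.normal(size=200), rng.normal(size=200)
        m = sq.mae_mse(yh, y)
        assert m.mae == pytest.approx(sum(abs(a - b) for a, b in zip(yh, y)) / 200, rel=1e-12)
        assert m.mse == pytest.approx(sum((a - b) ** 2 for a, b in zip(yh, y)) / 200, rel=1e-12)

    def test_all_excluded_rejected(self):
        with pytest.raises(ValueError):
            sq.mae_mse([1.0], [0.0], exclude=[0])

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_mae_mse_inequalities(self, seed):
        rng = np.random.default_rng(seed)
        yh, y = rng.normal(size=20), rng.normal(size=20)
        m = sq.mae_mse(yh, y)
        err = np.abs(yh - y)
        assert m.mae**2 <= m.mse + 1e-15
        assert m.mae <= err.max() + 1e-15
        assert math.sqrt(m.mse) <= err.max() + 1e-15


class TestEstimateConcentration:
    def test_point_examples(self):
        assert sq.estimate_concentration(math.log(2), 10.0) == pytest.approx(5.0)
        assert sq.estimate_concentration(0.0, 0.07) == pytest.approx(0.07)

    def test_factor_of_two_guarantee(self):
        # whenever |β̂ − β_true| <= ln 2, the estimate is within a factor of 2
        rng = np.random.default_rng(2)
        beta_true = rng.uniform(-1, 6, 500)
        beta_hat = beta_true + rng.uniform(-LN2, LN2, 500)
        c_true = rng.uniform(0.001, 0.1, 500)
        s_bar = np.exp(beta_true) * c_true
        ratio = sq.estimate_concentration(beta_hat, s_bar) / c_true
        assert np.all(ratio >= 0.5 - 1e-12) and np.all(ratio <= 2.0 + 1e-12)
        # boundary equality
        assert sq.estimate_concentration(1.0 + LN2, np.exp(1.0) * 0.05) == pytest.approx(0.025)

    def test_exact_beta_recovers_concentration(self, zero_noise_study):
        _, ds = zero_noise_study
        truth = {m.molecule_id: m.target for m in ds.molecules}
        m = ds.measurements
        s_bar = (m.area / m.istd_area).to_numpy()
        beta = m.molecule_id.map(truth).to_numpy(float)
        np.testing.assert_allclose(
            sq.estimate_concentration(beta, s_bar), m.concentration_mg_per_kg, rtol=1e-12
        )

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            sq.estimate_concentration(0.0, -1.0)


class TestCVHarness:
    @pytest.fixture()
    def small_table(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 4))
        y = X[:, 0] + rng.normal(0, 0.1, 10)
        return sq.DescriptorTable([f"m{i}" for i in range(10)], list("abcd"), X), y

    def test_loocv_emits_one_held_out_prediction_each(self, small_table):
        table, y = small_table
        rep = sq.run_cv(table, y, sq.MeanModelConfig(), sq.CVPlan(scheme="loocv", n_repeats=1))
        preds = rep.predictions["pred_run_0"]
        assert preds.notna().all() and len(preds) == 10
        for rec in rep.fold_records:
            assert set(rec.test_ids).isdisjoint(rec.train_ids)
            assert len(rec.train_ids) == 9

    def test_fold_hash_proves_test_isolation(self, small_table):
        table, y = small_table
        rep = sq.run_cv(table, y, sq.MeanModelConfig(), sq.CVPlan(scheme="loocv", n_repeats=1))
        for rec in rep.fold_records:
            idx = [table.molecule_ids.index(i) for i in rec.train_ids]
            recomputed = _hash_training_inputs(
                list(rec.train_ids), y[idx], np.ascontiguousarray(table.values[idx]).tobytes()
            )
            assert recomputed == rec.train_hash
            # perturbing the held-out molecule's features leaves the hash unchanged
            perturbed = table.values.copy()
            ti = table.molecule_ids.index(rec.test_ids[0])
            perturbed[ti] += 100.0
            assert (
                _hash_training_inputs(
                    list(rec.train_ids), y[idx], np.ascontiguousarray(perturbed[idx]).tobytes()
                )
                == rec.train_hash
            )

    def test_five_fold_sizes_on_ten_molecules(self, small_table):
        table, y = small_table
        rep = sq.run_cv(
            table, y, sq.MeanModelConfig(), sq.CVPlan(scheme="kfold", k=5, split_seed=42, n_repeats=1)
        )
        sizes = sorted(len(r.test_ids) for r in rep.fold_records)
        assert sizes == [2, 2, 2, 2, 2]
        tested = [i for r in rep.fold_records for i in r.test_ids]
        assert sorted(tested) == sorted(table.molecule_ids)

    def test_mean_model_loocv_matches_closed_form(self, small_table):
        table, y = small_table
        rep = sq.run_cv(table, y, sq.MeanModelConfig(), sq.CVPlan(scheme="loocv", n_repeats=1))
        n = len(y)
        expected = (y.sum() - y) / (n - 1)  # leave-one-out means
        np.testing.assert_allclose(rep.predictions["pred_run_0"], expected, rtol=1e-12)

    def test_subset_loocv_draws_differ_per_repeat(self, small_table):
        table, y = small_table
        rep = sq.run_cv(
            table,
            y,
            sq.MeanModelConfig(),
            sq.CVPlan(scheme="subset_loocv", subset_fraction=0.5, split_seed=1, n_repeats=2),
        )
        tested = {
            r: sorted({i for rec in rep.fold_records if rec.repeat == r for i in rec.test_ids})
            for r in (0, 1)
        }
        assert len(tested[0]) == 5
        assert tested[0] != tested[1]

    def test_invalid_plans_rejected(self):
        with pytest.raises(ConfigurationError):
            sq.CVPlan(scheme="bootstrap")
        with pytest.raises(ConfigurationError):
            sq.CVPlan(scheme="subset_loocv", subset_fraction=0.3)


class TestBuildReport:
    def _metric(self, acc):
        return sq.MetricSet(mae=acc, mse=acc, accuracy=acc, threshold=LN2, n=10)

    def test_single_run_zero_spread(self):
        rep = sq.build_report([self._metric(0.4)], pd.DataFrame({"molecule_id": []}))
        assert rep.summary()["accuracy"]["sd"] == 0.0

    def test_mean_and_sd_match_oracle(self):
        rep = sq.build_report([self._metric(v) for v in (0.4, 0.5, 0.6)], pd.DataFrame())
        s = rep.summary()
        assert s["accuracy"]["mean"] == pytest.approx(0.5)
        assert s["accuracy"]["sd"] == pytest.approx(np.std([0.4, 0.5, 0.6], ddof=1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sq.build_report([], pd.DataFrame())
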