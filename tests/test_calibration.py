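"""NIPALS PLS, segmented cross-validation, metrics and SECV selection."""

import numpy as np
import pytest

from aromacal import calibration as CA
from aromacal.spectra import SpectraSet, default_grid
from aromacal.synthetic_data import GeneratorConfig, simulate_dataset


class TestFitPLS:
    def test_single_informative_channel_exact_with_one_lv(self, rng):
        x = rng.normal(size=(20, 8))
        y = 3.0 * x[:, 2] + 1.0
        # make the other channels orthogonal noise-free distractors
        model = CA.fit_pls(np.column_stack([x[:, 2]]), y, 1)
        resid = y - model.predict(x[:, 2:3])
        assert np.max(np.abs(resid)) < 1e-8

    def test_full_rank_matches_minimum_norm_ols(self, rng):
        """At n_lv = rank, PLS equals the pseudoinverse OLS solution."""
        x = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        xc = x - x.mean(axis=0)
        beta_ols = np.linalg.pinv(xc) @ (y - y.mean())
        model = CA.fit_pls(x, y, 6)
        assert model.n_components == 6
        assert np.allclose(model.coefficients(), beta_ols, atol=1e-6)
        assert np.allclose(model.predict(x), y.mean() + xc @ beta_ols, atol=1e-6)

    def test_matches_sklearn_pls(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        x = rng.normal(size=(30, 12))
        y = x @ rng.normal(size=12) + 0.3 * rng.normal(size=30)
        mine = CA.fit_pls(x, y, 4)
        ref = PLSRegression(n_components=4, scale=False).fit(x, y[:, None])
        assert np.allclose(
            mine.predict(x), ref.predict(x).ravel(), atol=1e-8
        )

    def test_duplicating_samples_leaves_coefficients_unchanged(self, rng):
        x = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        a = CA.fit_pls(x, y, 3).coefficients()
        b = CA.fit_pls(np.vstack([x, x]), np.concatenate([y, y]), 3).coefficients()
        assert np.allclose(a, b, atol=1e-10)

    def test_one_lv_univariate_equals_simple_regression(self, rng):
        x = rng.normal(size=(25, 1))
        y = 2.0 * x[:, 0] + rng.normal(size=25)
        model = CA.fit_pls(x, y, 1)
        xc = x[:, 0] - x[:, 0].mean()
        slope = (xc @ (y - y.mean())) / (xc @ xc)
        assert model.coefficients()[0] == pytest.approx(slope, abs=1e-10)

    def test_score_vectors_orthogonal(self, rng):
        x = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        t = CA.fit_pls(x, y, 5).x_scores
        gram = t.T @ t
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="constant response"):
            CA.fit_pls(rng.normal(size=(5, 3)), np.ones(5), 1)

    def test_rank_exceeding_request_truncates_with_warning(self, rng):
        x = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        with pytest.warns(UserWarning, match="truncat"):
            model = CA.fit_pls(x, y, 10)
        assert model.n_components <= 3


class TestSegmentedCV:
    def test_block_sizes_for_36_samples_5_segments(self):
        sizes = [len(b) for b in CA.segments_of(36, 5)]
        assert sizes == [8, 7, 7, 7, 7]

    def test_blocks_are_contiguous_in_input_order(self):
        blocks = CA.segments_of(11, 3)
        flat = np.concatenate(blocks)
        assert np.array_equal(flat, np.arange(11))

    def test_leave_one_out_limit(self):
        blocks = CA.segments_of(7, 7)
        assert all(len(b) == 1 for b in blocks)

    def test_every_sample_predicted_once(self, small_dataset):
        ds = small_dataset
        y = ds.truth_scores["fruity"].to_numpy()
        y_cv = CA.segmented_cv(ds.spectra, y, CA.PretreatmentConfig(), 5)
        assert y_cv.shape == (60,)
        assert not np.isnan(y_cv).any()

    def test_noiseless_linear_data_cv_matches_fit(self):
        """When the model is exactly identifiable, held-out predictions
        coincide with training predictions."""
        cfg = GeneratorConfig(
            n_samples=60, seed=3, scatter_offset_sd=0.0,
            scatter_gain_log_sd=0.0, noise_sd=0.0,
        )
        ds = simulate_dataset(cfg)
        y = ds.truth_scores["microbiological"].to_numpy()
        config = CA.PretreatmentConfig()
        pre = CA.fit_pretreatment(ds.spectra.values, config, ds.spectra.step)
        model = CA.fit_pls(pre.transform(ds.spectra.values), y, 15)
        y_fit = model.predict(pre.transform(ds.spectra.values))
        y_cv = CA.segmented_cv(ds.spectra, y, config, 15)
        scale = np.std(y)
        assert np.allclose(y_cv / scale, y_fit / scale, atol=1e-6)

    def test_no_leakage_of_held_out_response(self, small_dataset):
        """Perturbing sample i's reference value must not change sample
        i's own cross-validated prediction."""
        ds = small_dataset
        y = ds.truth_scores["green_vegetative"].to_numpy().copy()
        config = CA.PretreatmentConfig(scatter="msc")
        base = CA.segmented_cv(ds.spectra, y, config, 6)
        for i in (0, 17, 59):
            y_pert = y.copy()
            y_pert[i] += 1000.0
            pert = CA.segmented_cv(ds.spectra, y_pert, config, 6)
            assert pert[i] == base[i]

    def test_too_few_training_samples_rejected(self):
        ss = SpectraSet(default_grid(), np.random.default_rng(0).normal(size=(3, 261)))
        with pytest.raises(ValueError):
            CA.segmented_cv(ss, np.array([1.0, 2.0, 3.0]), CA.PretreatmentConfig(), 1,
                            segments=2)


class TestMetrics:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = CA.compute_metrics(y, y, y, 1)
        assert m.r2_c == pytest.approx(1.0)
        assert m.sec == 0.0
        assert m.rpd == np.inf

    def test_hand_computed_oracle(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        y_cv = np.array([1.1, 1.9, 3.2, 3.8])
        m = CA.compute_metrics(y, y, y_cv, 1)
        r = np.corrcoef(y, y_cv)[0, 1]
        sse = 0.1**2 + 0.1**2 + 0.2**2 + 0.2**2
        assert m.r2_cv == pytest.approx(r**2, abs=1e-12)
        assert m.secv == pytest.approx(np.sqrt(sse / 4), abs=1e-12)
        assert m.rpd == pytest.approx(np.std(y, ddof=1) / np.sqrt(sse / 4))

    def test_scale_equivariance(self, rng):
        y = rng.normal(size=12)
        y_fit = y + rng.normal(0, 0.1, size=12)
        y_cv = y + rng.normal(0, 0.2, size=12)
        m1 = CA.compute_metrics(y, y_fit, y_cv, 2)
        m2 = CA.compute_metrics(2 * y, 2 * y_fit, 2 * y_cv, 2)
        assert m2.r2_c == pytest.approx(m1.r2_c)
        assert m2.r2_cv == pytest.approx(m1.r2_cv)
        assert m2.sec == pytest.approx(2 * m1.sec)
        assert m2.secv == pytest.approx(2 * m1.secv)

    def test_sec_non_increasing_in_lv(self, small_dataset):
        ds = small_dataset
        y = ds.truth_scores["fruity"].to_numpy()
        pre = CA.fit_pretreatment(
            ds.spectra.values, CA.PretreatmentConfig(), ds.spectra.step
        )
        xt = pre.transform(ds.spectra.values)
        model = CA.fit_pls(xt, y, 12)
        sse = [
            float(np.sum((y - model.predict(xt, a)) ** 2))
            for a in range(1, model.n_components + 1)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(sse, sse[1:]))


class TestModelSelection:
    def test_noiseless_data_selected_model_is_near_exact(self):
        cfg = GeneratorConfig(
            n_samples=60, seed=5, scatter_offset_sd=0.0,
            scatter_gain_log_sd=0.0, noise_sd=0.0,
        )
        ds = simulate_dataset(cfg)
        res = CA.model_selection(
            ds.spectra, ds.truth_scores["green_vegetative"].to_numpy()
        )
        assert res.metrics.r2_cv > 0.999

    def test_grid_covers_all_cells(self, small_dataset):
        ds = small_dataset
        res = CA.model_selection(
            ds.spectra, ds.truth_scores["fruity"].to_numpy(), lv_max=6
        )
        assert set(res.grid["pretreatment"]) == {"none", "snv", "msc"}
        assert res.grid.shape[0] == 3 * 6
        winner = res.grid[
            (res.grid["pretreatment"] == res.pretreatment)
            & (res.grid["n_lv"] == res.n_components)
        ]
        assert winner["secv"].iloc[0] == res.grid["secv"].min()

    def test_tie_breaks_smaller_lv_then_pretreatment_order(self):
        rows = [
            {"pretreatment": "msc", "n_lv": 2, "secv": 1.0},
            {"pretreatment": "snv", "n_lv": 2, "secv": 1.0},
            {"pretreatment": "none", "n_lv": 3, "secv": 1.0},
        ]
        best = CA.select_best_cell(rows)
        assert (best["pretreatment"], best["n_lv"]) == ("snv", 2)
        rows.append({"pretreatment": "msc", "n_lv": 1, "secv": 1.0})
        assert CA.select_best_cell(rows)["n_lv"] == 1

    def test_strong_scatter_favors_scatter_correction(self):
        """Under strong multiplicative scatter a scatter-correcting
        pretreatment wins model selection in >= 90% of 20 replicates."""
        wins = 0
        for seed in range(20):
            cfg = GeneratorConfig(
                n_samples=60, seed=1000 + seed,
                scatter_offset_sd=0.3, scatter_gain_log_sd=0.3, noise_sd=0.002,
            )
            ds = simulate_dataset(cfg)
            res = CA.model_selection(
                ds.spectra, ds.truth_scores["green_vegetative"].to_numpy()
            )
            wins += res.pretreatment in ("snv", "msc")
        assert wins >= 18
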