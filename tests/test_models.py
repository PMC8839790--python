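"""Chemometric models: blocked CV, PCA, PCA-LDA, PLSR, optimizers,
subtraction spectra."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from aquahoney import (
    DEFAULT_PARAMS,
    ModelTask,
    PCALDAModel,
    PLSRModel,
    cross_validate,
    cv_plsr,
    fit_pca,
    generate_design,
    generate_spectra,
    loso_folds,
    optimize_pretreatment,
    subtraction_spectra,
)
from aquahoney.exceptions import (
    ClassSupportError,
    DegenerateTargetError,
    DimensionError,
    FoldError,
)
from aquahoney.models import (
    fit_pca_lda,
    permuted_null_accuracy,
    select_rank,
)
from aquahoney.spectra import CONTROL

from conftest import toy_spectra


def separable_spectra():
    """Noise-free study subset: dose-separated classes, identical bottles."""
    params = replace(
        DEFAULT_PARAMS,
        scatter_sd=0.0,
        offset_sd=0.0,
        scan_noise_sd=0.0,
        archetypes=tuple(
            replace(a, replicate_sd=0.0, dose_response_sd=0.0)
            for a in DEFAULT_PARAMS.archetypes
        ),
    )
    return generate_spectra(generate_design(("sunflower",)), params)


class TestLosoFolds:
    def test_three_replicate_blocked_folds(self, study_spectra):
        meta = study_spectra.subset(honey_type="sunflower").meta
        folds = loso_folds(meta)
        assert len(folds) == 3
        all_val = np.concatenate([va for _, _, va in folds])
        assert sorted(all_val) == list(range(len(meta)))
        for rep, tr, va in folds:
            assert len(va) == 255  # 765 spectra / 3 replicates
            assert set(tr).isdisjoint(va)
            assert (meta.iloc[va]["replicate"] == rep).all()
            assert (meta.iloc[tr]["replicate"] != rep).all()

    def test_no_sample_straddles_a_fold(self, study_spectra):
        s = study_spectra.subset(honey_type="acacia")
        ids = s.sample_ids().to_numpy()
        for _, tr, va in loso_folds(s.meta):
            assert set(ids[tr]).isdisjoint(ids[va])

    def test_single_replicate_rejected(self):
        meta = toy_spectra().meta.assign(replicate="R1")
        with pytest.raises(FoldError):
            loso_folds(meta)


class TestPca:
    def test_one_dimensional_data_explains_everything(self):
        rng = np.random.default_rng(0)
        direction = rng.standard_normal(8)
        X = np.outer(rng.standard_normal(20), direction) + 3.0
        m = fit_pca(X, 2)
        assert m.explained_variance_ratio[0] == pytest.approx(100.0, abs=1e-9)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 12))
        m = fit_pca(X, 5)
        np.testing.assert_allclose(m.loadings @ m.loadings.T, np.eye(5), atol=1e-8)

    def test_matches_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 8))
        m = fit_pca(X, 8)
        cov = np.cov(X, rowvar=False, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        # explained variance per PC equals the covariance eigenvalues
        var = (X - X.mean(0)).shape[0] - 1
        ev = m.explained_variance_ratio / 100 * eigvals.sum()
        np.testing.assert_allclose(ev, eigvals[:8], atol=1e-9)
        # scores reproduce the data in the loading basis
        recon = m.scores @ m.loadings + m.mean_
        np.testing.assert_allclose(recon, X, atol=1e-9)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((15, 6))
        a = fit_pca(X, 3)
        b = fit_pca(X.copy(), 3)
        np.testing.assert_array_equal(a.loadings, b.loadings)
        k = np.argmax(np.abs(a.loadings), axis=1)
        assert (a.loadings[np.arange(3), k] > 0).all()

    def test_rank_bounds_enforced(self):
        with pytest.raises(DimensionError):
            fit_pca(np.ones((5, 4)), 5)


class TestPcaLda:
    def test_planted_separation_classified_perfectly(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 10))
        X[30:, 0] += 20.0  # 20 sigma apart along the dominant direction
        y = np.array(["a"] * 30 + ["b"] * 30)
        fit = fit_pca_lda(X, y, 2)
        assert (fit.predict(X) == y).all()

    def test_wavelength_weights_shape(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 12))
        y = np.repeat(["a", "b", "c", "d"], 10)
        fit = fit_pca_lda(X, y, 5)
        assert fit.wavelength_weights.shape == (3, 12)  # k-1 axes x wavelengths

    def test_class_with_single_sample_rejected(self):
        X = np.random.default_rng(6).standard_normal((11, 5))
        y = np.array(["a"] * 10 + ["b"])
        with pytest.raises(ClassSupportError):
            fit_pca_lda(X, y, 3)

    def test_permuted_labels_score_at_chance(self, study_spectra_cut):
        task = ModelTask("general_temperature", "sunflower")
        accs = permuted_null_accuracy(
            study_spectra_cut, task, "snv", n_pcs=10, n_permutations=5, seed=0
        )
        assert np.all(accs > 5) and np.all(accs < 35)  # 5 classes -> ~20%


class TestRankSelection:
    def test_validation_first_then_gap(self):
        table = pd.DataFrame(
            {"n_pcs": [2, 3, 4], "validation": [90, 95, 95], "gap": [2, 8, 3]}
        )
        assert select_rank(table) == 4

    def test_single_candidate_returned(self):
        table = pd.DataFrame({"n_pcs": [7], "validation": [50], "gap": [10]})
        assert select_rank(table) == 7

    def test_full_tie_takes_smallest_rank(self):
        table = pd.DataFrame(
            {"n_pcs": [5, 3, 9], "validation": [80, 80, 80], "gap": [1, 1, 1]}
        )
        assert select_rank(table) == 3


class TestCrossValidate:
    def test_separable_classes_score_100(self):
        s = separable_spectra()
        from aquahoney import cut_range

        task = ModelTask("detailed_temperature", "sunflower", 240)
        cv = cross_validate(cut_range(s, 1300, 1600), task, "raw", 4)
        assert cv.training_accuracy == 100.0
        assert cv.validation_accuracy == 100.0
        assert cv.control_accuracy == 100.0

    def test_pooled_confusion_rows_are_45_per_level(self, study_spectra_cut):
        task = ModelTask("detailed_temperature", "sunflower", 60)
        cv = cross_validate(study_spectra_cut, task, "snv", 8)
        pooled = cv.pooled_confusion
        assert (pooled.sum(axis=1) == 45).all()

    def test_control_accuracy_definition(self, study_spectra_cut):
        task = ModelTask("detailed_temperature", "sunflower", 240)
        cv = cross_validate(study_spectra_cut, task, "snv", 8)
        pooled = cv.pooled_confusion
        expected = 100.0 * pooled.loc[CONTROL, CONTROL] / pooled.loc[CONTROL].sum()
        assert cv.control_accuracy == pytest.approx(expected)


class TestOptimizePretreatment:
    def test_scatter_correction_beats_raw_on_scattered_data(self):
        params = replace(
            DEFAULT_PARAMS.with_seed(5),
            scatter_sd=0.6,
            offset_sd=0.0,
            scan_noise_sd=0.001,
        )
        s = generate_spectra(generate_design(("sunflower",)), params)
        from aquahoney import cut_range
        from aquahoney.pretreat import parse_spec

        sc = cut_range(s, 1300, 1600)
        task = ModelTask("detailed_temperature", "sunflower", 240)
        grid = [parse_spec("raw"), parse_spec("snv")]
        best, report = optimize_pretreatment(sc, task, grid, pc_candidates=(4, 6))
        assert best.format() == "snv"
        vals = dict(zip(report["pretreatment"], report["validation"]))
        assert vals["snv"] > vals["raw"]

    def test_tie_resolves_to_grid_order(self):
        from aquahoney import cut_range
        from aquahoney.pretreat import parse_spec

        s = cut_range(separable_spectra(), 1300, 1600)
        task = ModelTask("detailed_temperature", "sunflower", 240)
        grid = [parse_spec("snv"), parse_spec("snv")]
        best, report = optimize_pretreatment(s, task, grid, pc_candidates=(3,))
        assert best is grid[0]
        assert len(report) == 2


class TestPlsr:
    def _linear_band_target(self):
        s = separable_spectra()
        from aquahoney import cut_range

        sc = cut_range(s, 1300, 1600)
        return sc

    def test_noiseless_linear_target_fits_perfectly(self):
        # spectra whose 1412 nm band grows exactly linearly with time
        from aquahoney import SpectraSet, WavelengthGrid

        wl = 1300.0 + 3.0 * np.arange(101)
        base = 0.5 + 0.2 * np.exp(-0.5 * ((wl - 1450) / 20) ** 2)
        band = np.exp(-0.5 * ((wl - 1412) / 15) ** 2)
        rows, meta_rows = [], []
        for t in (0, 60, 120, 180, 240):
            for r in ("R1", "R2", "R3"):
                rows.append(base + 1e-3 * t * band)
                meta_rows.append(
                    ("sunflower", CONTROL if t == 0 else 40, t, r, 1, 1)
                )
        meta = pd.DataFrame(
            meta_rows,
            columns=["honey_type", "temperature_C", "time_min", "replicate", "fill", "scan"],
        )
        s = SpectraSet(WavelengthGrid(wl), np.array(rows), meta)
        rep = cv_plsr(s, ModelTask("general_time", "sunflower"), "raw", max_lvs=4)
        assert rep.RMSECV == pytest.approx(0.0, abs=1e-6)
        assert rep.R2CV == pytest.approx(1.0, abs=1e-6)

    def test_rpd_identity_to_1e9(self, study_spectra_cut):
        task = ModelTask("general_temperature", "sunflower")
        rep = cv_plsr(study_spectra_cut, task, "sgol@2-21-0_snv")
        sd = float(np.std(rep.y_true))
        assert rep.RPDCV == pytest.approx(sd / rep.RMSECV, abs=1e-9)
        assert rep.RPDC == pytest.approx(sd / rep.RMSEC, abs=1e-9)
        assert rep.R2CV == pytest.approx(1 - 1 / rep.RPDCV**2, abs=1e-9)

    def test_constant_target_rejected(self):
        sc = self._linear_band_target().subset(temperature_C=CONTROL)
        task = ModelTask("general_time", "sunflower")
        with pytest.raises(DegenerateTargetError):
            cv_plsr(sc, task, "raw")

    def test_matches_brute_force_nipals_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 6))
        y = rng.standard_normal(30)

        def nipals_pls1(X, y, a):
            Xk = X - X.mean(0)
            yk = y - y.mean()
            W, P, Q = [], [], []
            for _ in range(a):
                w = Xk.T @ yk
                w = w / np.linalg.norm(w)
                t = Xk @ w
                p = Xk.T @ t / (t @ t)
                q = (yk @ t) / (t @ t)
                Xk = Xk - np.outer(t, p)
                yk = yk - q * t
                W.append(w)
                P.append(p)
                Q.append(q)
            W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
            return W @ np.linalg.inv(P.T @ W) @ Q

        from aquahoney.models import _pls_coefs_per_lv

        for a in (1, 2):
            B = _pls_coefs_per_lv(X, y, 2)[a - 1].ravel()
            np.testing.assert_allclose(B, nipals_pls1(X, y, a), atol=1e-8)

    def test_full_rank_pls_equals_least_squares(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 5))
        beta = rng.standard_normal(5)
        y = X @ beta + 2.0
        from aquahoney.models import _pls_coefs_per_lv

        B = _pls_coefs_per_lv(X, y, 5)[-1].ravel()
        np.testing.assert_allclose(B, beta, atol=1e-6)


class TestModelResultsApi:
    def test_pcalda_results_summary_reports_cv_metrics(self, study_spectra_cut):
        task = ModelTask("detailed_temperature", "sunflower", 240)
        res = PCALDAModel(study_spectra_cut, task, "snv", n_pcs=6).fit()
        text = res.summary()
        assert "Validation acc." in text and "snv" in text
        assert res.wavelength_weights.shape[1] == study_spectra_cut.grid.n_wavelengths

    def test_plsr_results_summary(self, study_spectra_cut):
        task = ModelTask("general_temperature", "sunflower")
        res = PLSRModel(study_spectra_cut, task, "snv", max_lvs=6).fit()
        assert "R2CV" in res.summary()
        assert len(res.regression_vector) == study_spectra_cut.grid.n_wavelengths


class TestSubtractionSpectra:
    def test_equal_group_means_give_identical_differences(self):
        s = separable_spectra()
        from aquahoney import cut_range

        sc = cut_range(s, 1300, 1600).subset(time_min=[0, 60])
        d = subtraction_spectra(sc, "temperature_C", "msc")
        # the control row is omitted (identically zero); groups are the 4 temps
        assert list(d.index) == [40, 60, 80, 100]

    def test_control_equal_to_itself_is_zero(self):
        s = separable_spectra()
        from aquahoney import SpectraSet, cut_range

        sc = cut_range(s, 1300, 1600)
        ctrl = sc.subset(temperature_C=CONTROL)
        relabeled = ctrl.meta.copy()
        relabeled.loc[relabeled.index[:30], ["temperature_C", "time_min"]] = [40, 60]
        twin = SpectraSet(ctrl.grid, ctrl.absorbance, relabeled)
        d = subtraction_spectra(twin, "temperature_C", "msc")
        np.testing.assert_allclose(d.loc[40].to_numpy(), 0.0, atol=1e-9)

    def test_dose_effect_peaks_near_perturbed_band(self, study_spectra_cut):
        comp = study_spectra_cut.subset(honey_type="sunflower", time_min=[0, 240])
        d = subtraction_spectra(comp, "temperature_C", "msc")
        diff = d.loc[100]
        wl = diff.index.to_numpy(dtype=float)
        peak = wl[np.argmax(np.abs(diff.to_numpy()))]
        band_centers = (1412.0, 1490.0, 1512.0)
        assert min(abs(peak - c) for c in band_centers) <= 6.0
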