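import numpy as np
import pandas as pd
import pytest

from connharm.errors import DataError, LeakageError, UsageError
from connharm.harmonization import (
    ConfoundModel,
    SiteCalibration,
    apply_calibration,
    apply_confound_model,
    calibrate_new_site,
    fit_confound_model,
)
from connharm.synthetic_data import SyntheticConfig, generate_fc_cohort


def _fit(cohort, **kw):
    return fit_confound_model(np.asarray(cohort.features), cohort.phenotypes, **kw)


class TestFitConfoundModel:
    def test_site_contrasts_recovered(self):
        cfg = SyntheticConfig(
            n_sites=4, n_hc_per_site=50, n_mdd_per_site=50, n_rois=10,
            effect_size=0.0, effect_fraction=0.0, site_offset_sd=1.0, seed=41,
        )
        c = generate_fc_cohort(cfg)
        model = _fit(c)
        est = model.site_offsets - model.site_offsets.mean(0)
        true = c.truth.site_offsets - c.truth.site_offsets.mean(0)
        assert np.corrcoef(est.ravel(), true.ravel())[0, 1] > 0.95

    def test_single_site_reduces_to_intercept_fit(self):
        cfg = SyntheticConfig(n_sites=1, n_hc_per_site=20, n_mdd_per_site=20, n_rois=8, seed=42)
        c = generate_fc_cohort(cfg)
        model, resid = _fit(c, return_residuals=True)
        assert model.site_list == ["site01"]
        # the single dummy is the site's adjusted intercept; residuals mean-zero
        assert np.abs(resid.mean(0)).max() < 1e-8

    def test_training_residuals_mean_zero_per_site(self, biased_cohort):
        model, resid = fit_confound_model(
            np.asarray(biased_cohort.features), biased_cohort.phenotypes, return_residuals=True
        )
        for s in model.site_list:
            m = (biased_cohort.phenotypes["site"] == s).to_numpy()
            assert np.abs(resid[m].mean(0)).max() < 1e-8

    def test_small_site_rejected(self, biased_cohort):
        ph = biased_cohort.phenotypes.copy()
        ph.loc[ph.index[-1], "site"] = "lonely"
        with pytest.raises(DataError, match="lonely"):
            fit_confound_model(np.asarray(biased_cohort.features), ph)

    def test_missing_covariate_names_subjects(self, biased_cohort):
        ph = biased_cohort.phenotypes.copy()
        ph.loc[ph.index[2], "age"] = np.nan
        with pytest.raises(DataError, match=ph["id"].iloc[2]):
            fit_confound_model(np.asarray(biased_cohort.features), ph)


class TestApplyConfoundModel:
    def test_training_set_gives_training_residuals(self, biased_cohort):
        X = np.asarray(biased_cohort.features)
        model, resid = fit_confound_model(X, biased_cohort.phenotypes, return_residuals=True)
        np.testing.assert_allclose(
            apply_confound_model(model, X, biased_cohort.phenotypes), resid, atol=1e-10
        )

    def test_reference_subject_residual_is_feature_minus_site_offset(self, biased_cohort):
        X = np.asarray(biased_cohort.features)
        model = fit_confound_model(X, biased_cohort.phenotypes)
        site = model.site_list[0]
        ph = pd.DataFrame(
            {"id": ["q1"], "site": [site], "age": [model.age_center], "sex": [0]}
        )
        x = np.ones((1, model.n_edges))
        resid = apply_confound_model(model, x, ph)
        np.testing.assert_allclose(resid[0], 1.0 - model.site_offsets[0], atol=1e-10)

    def test_unknown_site_rejected_with_guidance(self, biased_cohort):
        X = np.asarray(biased_cohort.features)
        model = fit_confound_model(X, biased_cohort.phenotypes)
        ph = biased_cohort.phenotypes.copy()
        ph["site"] = "elsewhere"
        with pytest.raises(UsageError, match="calibrate_new_site"):
            apply_confound_model(model, X, ph)

    def test_harmonization_removes_site_predictability(self):
        # fold-internal harmonization: fit the confound model on the training
        # fold only, then ask a site classifier to identify held-out subjects
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import StratifiedKFold

        cfg = SyntheticConfig(
            n_sites=4, n_hc_per_site=25, n_mdd_per_site=25, n_rois=10,
            effect_size=0.0, effect_fraction=0.0, site_offset_sd=1.0, seed=44,
        )
        c = generate_fc_cohort(cfg)
        X = np.asarray(c.features)
        ph = c.phenotypes
        sites = ph["site"].to_numpy()
        hits_raw = hits_harm = 0
        for tr, te in StratifiedKFold(5, shuffle=True, random_state=0).split(X, sites):
            clf = LogisticRegression(max_iter=2000).fit(X[tr], sites[tr])
            hits_raw += (clf.predict(X[te]) == sites[te]).sum()
            model = fit_confound_model(X[tr], ph.iloc[tr])
            r_tr = apply_confound_model(model, X[tr], ph.iloc[tr])
            r_te = apply_confound_model(model, X[te], ph.iloc[te])
            clf2 = LogisticRegression(max_iter=2000).fit(r_tr, sites[tr])
            hits_harm += (clf2.predict(r_te) == sites[te]).sum()
        acc_before = hits_raw / len(sites)
        acc_after = hits_harm / len(sites)
        assert acc_before > 0.9  # raw features carry strong site signature
        assert abs(acc_after - 0.25) <= 0.05  # chance for 4 sites

    def test_idempotence_on_residuals(self, biased_cohort):
        # refitting on harmonized features finds nothing left to remove
        X = np.asarray(biased_cohort.features)
        model, resid = fit_confound_model(X, biased_cohort.phenotypes, return_residuals=True)
        model2, resid2 = fit_confound_model(resid, biased_cohort.phenotypes, return_residuals=True)
        np.testing.assert_allclose(resid2, resid, atol=1e-8)


class TestCalibration:
    @staticmethod
    def _train_and_new_site(seed=45, delta_scale=1.0, n_cal=30, effect_size=0.0):
        cfg = SyntheticConfig(
            n_sites=4, n_hc_per_site=30, n_mdd_per_site=30, n_rois=8,
            effect_size=effect_size, effect_fraction=0.1 if effect_size else 0.0,
            site_offset_sd=0.0, seed=seed,
        )
        c = generate_fc_cohort(cfg)
        X = np.asarray(c.features)
        model = fit_confound_model(X, c.phenotypes)
        rng = np.random.default_rng(seed + 1)
        delta = rng.normal(0, delta_scale, size=cfg.n_edges)
        from connharm.synthetic_data import GroundTruth, generate_phenotypes, _noise_free_features

        new_cfg = SyntheticConfig(
            n_sites=1, n_hc_per_site=n_cal + 20, n_mdd_per_site=1, n_rois=8,
            effect_size=0.0, effect_fraction=0.0, site_offset_sd=0.0, seed=seed + 2,
        )
        ph = generate_phenotypes(new_cfg, rng)
        ph["site"] = "newsite"
        truth = GroundTruth(
            site_offsets=delta[None, :],
            effect_mask=c.truth.effect_mask,
            true_betas=c.truth.true_betas,
            affected_edges=c.truth.affected_edges,
            baseline_mean=c.truth.baseline_mean,
            site_names=["newsite"],
        )
        Z = _noise_free_features(new_cfg, ph, truth)
        X_new = Z + rng.normal(0, 1.0, size=Z.shape)
        return c, model, ph, X_new, delta

    def test_planted_offset_recovered(self):
        c, model, ph, X_new, delta = self._train_and_new_site()
        hc = np.flatnonzero(ph["diagnosis"] == "HC")[:30]
        cal = calibrate_new_site(model, X_new[hc], ph.iloc[hc])
        expected = delta + c.truth.baseline_mean
        tol = 3.0 / np.sqrt(30)
        assert np.mean(np.abs(cal.offset - expected) < tol) >= 0.95

    def test_new_site_hc_residuals_centered(self):
        c, model, ph, X_new, delta = self._train_and_new_site(delta_scale=0.0, n_cal=40)
        hc = np.flatnonzero(ph["diagnosis"] == "HC")
        cal_idx, test_idx = hc[:40], hc[40:]
        cal = calibrate_new_site(model, X_new[cal_idx], ph.iloc[cal_idx])
        resid = apply_calibration(model, cal, X_new[test_idx], ph.iloc[test_idx])
        se = 1.0 / np.sqrt(len(test_idx))
        assert np.mean(np.abs(resid.mean(0)) < 2 * (se + 1.0 / np.sqrt(40))) > 0.9

    def test_offset_and_refit_agree_on_balanced_noise_free_case(self):
        c, model, ph, X_new, delta = self._train_and_new_site()
        X = np.asarray(c.features)
        # noise-free, covariate-balanced calibration set
        ages = model.age_center + np.array([-5.0, 5.0, -5.0, 5.0])
        sexes = [0, 1, 0, 1]
        cal_ph = pd.DataFrame(
            {"id": [f"b{i}" for i in range(4)], "site": "bal", "age": ages,
             "sex": sexes, "diagnosis": "HC"}
        )
        hc_anchor = model.hc_residual_mean
        X_cal = (
            delta[None, :]
            + (ages - model.age_center)[:, None] * model.beta_age[None, :]
            + np.array(sexes, dtype=float)[:, None] * model.beta_sex[None, :]
            + hc_anchor[None, :]
        )
        a = calibrate_new_site(model, X_cal, cal_ph, method="offset")
        b = calibrate_new_site(
            model, X_cal, cal_ph, method="refit", X_train=X, pheno_train=c.phenotypes
        )
        np.testing.assert_allclose(a.offset, b.offset, atol=1e-6)

    def test_calibration_requires_healthy_controls_from_one_site(self, biased_cohort):
        X = np.asarray(biased_cohort.features)
        model = fit_confound_model(X, biased_cohort.phenotypes)
        rows = np.r_[0:2, 12:14]  # two controls and two patients from site01
        ph = biased_cohort.phenotypes.iloc[rows].copy()
        assert set(ph["diagnosis"]) == {"HC", "MDD"}
        ph["site"] = "new"
        with pytest.raises(UsageError, match="healthy controls"):
            calibrate_new_site(model, X[rows], ph)  # contains patients
        ph2 = ph.copy()
        ph2["diagnosis"] = "HC"
        ph2.loc[ph2.index[0], "site"] = "other"
        with pytest.raises(UsageError, match="multiple sites"):
            calibrate_new_site(model, X[rows], ph2)

    def test_scoring_calibration_subjects_is_leakage(self):
        c, model, ph, X_new, delta = self._train_and_new_site()
        hc = np.flatnonzero(ph["diagnosis"] == "HC")
        cal = calibrate_new_site(model, X_new[hc[:10]], ph.iloc[hc[:10]])
        with pytest.raises(LeakageError):
            apply_calibration(model, cal, X_new[hc[:10]], ph.iloc[hc[:10]])
        # explicit override works
        out = apply_calibration(
            model, cal, X_new[hc[:10]], ph.iloc[hc[:10]], allow_calibration_overlap=True
        )
        assert out.shape == (10, model.n_edges)


class TestSerialization:
    def test_confound_model_json_roundtrip(self, tmp_path, biased_cohort):
        X = np.asarray(biased_cohort.features)
        model = fit_confound_model(X, biased_cohort.phenotypes)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ConfoundModel.from_json(path)
        np.testing.assert_allclose(back.site_offsets, model.site_offsets)
        np.testing.assert_allclose(back.hc_residual_mean, model.hc_residual_mean)
        assert back.site_list == model.site_list

    def test_site_calibration_json_roundtrip(self, tmp_path):
        cal = SiteCalibration("s", np.arange(4.0), 3, ["a", "b", "c"])
        path = tmp_path / "cal.json"
        cal.to_json(path)
        back = SiteCalibration.from_json(path)
        np.testing.assert_allclose(back.offset, cal.offset)
        assert back.calibration_ids == cal.calibration_ids
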