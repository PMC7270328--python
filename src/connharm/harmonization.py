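"""Confound regression and independent-site calibration.

Fisher-z connectivity features are linearly regressed, edge by edge, on the
training subjects' age, sex, and one indicator variable per acquisition site
(cell-means coding: one dummy per site and no global intercept, so each
site coefficient is directly that site's adjusted mean).  The residuals are
the harmonized features; the fitted coefficients are reused to residualize
test subjects, so no test-set statistic ever enters the fit.

A site never seen in training has no dummy.  Its additive offset is instead
estimated from a designated subset of that site's healthy controls
(:func:`calibrate_new_site`): with the training age/sex coefficients frozen,
the new site's offset is the calibration-control mean of the
covariate-adjusted features.  The remaining (non-calibration) subjects of
that site are then residualized with :func:`apply_calibration`; subject-id
bookkeeping refuses to score a calibration subject unless explicitly
overridden.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from connharm.errors import DataError, LeakageError, UsageError

logger = logging.getLogger(__name__)


def _encode_sex(values, mapping: dict | None = None):
    """Map a sex column to {0, 1}; accepts 0/1, 'M'/'F', 'male'/'female'.

    Returns (codes, mapping).  The mapping is stored in the model so the same
    coding is applied at prediction time.
    """
    vals = pd.Series(values)
    if mapping is None:
        uniq = sorted({str(v) for v in vals.unique()})
        if set(uniq) <= {"0", "1", "0.0", "1.0"}:
            mapping = {u: int(float(u)) for u in uniq}
        elif len(uniq) <= 2:
            mapping = {u: i for i, u in enumerate(uniq)}
            logger.info("sex coding: %s", mapping)
        else:
            raise DataError(f"sex column has more than two levels: {uniq}")
    try:
        codes = vals.astype(str).map(mapping).to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"unmappable sex values: {exc}") from exc
    if np.any(np.isnan(codes)):
        raise DataError("sex values outside the model's stored coding")
    return codes, mapping


@dataclass
class ConfoundModel:
    """Per-edge OLS coefficients for age, sex and site, fitted on training subjects."""

    site_list: list
    site_offsets: np.ndarray  # (n_sites, n_edges)
    beta_age: np.ndarray  # (n_edges,)
    beta_sex: np.ndarray  # (n_edges,)
    age_center: float
    sex_coding: dict = field(default_factory=dict)
    #: per-edge mean training residual of the healthy controls.  When the
    #: confound fit pools patients and controls, each site dummy absorbs part
    #: of the diagnosis effect, so control residuals do not center at zero;
    #: calibration anchors a new site's controls to this structure.
    hc_residual_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.site_list) == 0:
            raise DataError("site_list must be non-empty")
        if len(set(self.site_list)) != len(self.site_list):
            raise DataError("duplicate sites in site_list")
        E = self.site_offsets.shape[1]
        if self.beta_age.shape != (E,) or self.beta_sex.shape != (E,):
            raise DataError("coefficient arrays disagree on edge dimension")

    @property
    def n_edges(self) -> int:
        return self.site_offsets.shape[1]

    def predict(self, pheno: pd.DataFrame) -> np.ndarray:
        """Expected confound contribution per subject per edge."""
        site_idx = []
        for s in pheno["site"]:
            if s not in self.site_list:
                raise UsageError(
                    f"site '{s}' was not in training; use calibrate_new_site / apply_calibration"
                )
            site_idx.append(self.site_list.index(s))
        age_c = pheno["age"].to_numpy(dtype=float) - self.age_center
        sex, _ = _encode_sex(pheno["sex"], self.sex_coding)
        return (
            self.site_offsets[site_idx]
            + age_c[:, None] * self.beta_age[None, :]
            + sex[:, None] * self.beta_sex[None, :]
        )

    def covariate_adjust(self, X: np.ndarray, pheno: pd.DataFrame) -> np.ndarray:
        """Remove only the age and sex terms (no site term)."""
        age_c = pheno["age"].to_numpy(dtype=float) - self.age_center
        sex, _ = _encode_sex(pheno["sex"], self.sex_coding)
        return X - age_c[:, None] * self.beta_age[None, :] - sex[:, None] * self.beta_sex[None, :]

    def to_json(self, path, edge_names=None) -> None:
        obj = {
            "site_list": list(self.site_list),
            "site_offsets": self.site_offsets.tolist(),
            "beta_age": self.beta_age.tolist(),
            "beta_sex": self.beta_sex.tolist(),
            "age_center": self.age_center,
            "sex_coding": self.sex_coding,
            "hc_residual_mean": self.hc_residual_mean.tolist()
            if self.hc_residual_mean is not None
            else None,
            "edge_names": list(edge_names) if edge_names is not None else None,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path) -> "ConfoundModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            site_list=obj["site_list"],
            site_offsets=np.asarray(obj["site_offsets"], dtype=float),
            beta_age=np.asarray(obj["beta_age"], dtype=float),
            beta_sex=np.asarray(obj["beta_sex"], dtype=float),
            age_center=float(obj["age_center"]),
            sex_coding=obj["sex_coding"],
            hc_residual_mean=np.asarray(obj["hc_residual_mean"], dtype=float)
            if obj.get("hc_residual_mean") is not None
            else None,
        )


@dataclass
class SiteCalibration:
    """Per-edge additive offset of a previously unseen site, from its healthy controls."""

    site_name: str
    offset: np.ndarray  # (n_edges,)
    n_calibration: int
    calibration_ids: list

    def __post_init__(self) -> None:
        if self.n_calibration < 1:
            raise UsageError("calibration requires at least one healthy control")

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "site_name": self.site_name,
                    "offset": self.offset.tolist(),
                    "n_calibration": self.n_calibration,
                    "calibration_ids": list(self.calibration_ids),
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "SiteCalibration":
        obj = json.loads(Path(path).read_text())
        return cls(
            site_name=obj["site_name"],
            offset=np.asarray(obj["offset"], dtype=float),
            n_calibration=int(obj["n_calibration"]),
            calibration_ids=obj["calibration_ids"],
        )


def _check_pheno(pheno: pd.DataFrame, required=("site", "age", "sex")) -> None:
    missing_cols = [c for c in required if c not in pheno.columns]
    if missing_cols:
        raise DataError(f"phenotype table missing columns: {missing_cols}")
    for col in required:
        bad = pheno.index[pheno[col].isna()]
        if len(bad):
            ids = pheno.loc[bad, "id"].tolist() if "id" in pheno.columns else bad.tolist()
            raise DataError(f"missing '{col}' for subjects {ids}")


def fit_confound_model(
    X: np.ndarray,
    pheno: pd.DataFrame,
    return_residuals: bool = False,
):
    """Edge-wise OLS of features on [site dummies (cell means), centered age, sex].

    Every training subject needs site, age and sex; every site needs at least
    two subjects.  With a single site the site dummy is simply that site's
    adjusted intercept.  Returns the model, or ``(model, residuals)`` when
    ``return_residuals``.
    """
    X = np.asarray(X, dtype=float)
    _check_pheno(pheno)
    if X.shape[0] != len(pheno):
        raise DataError("feature rows and phenotype rows disagree")
    counts = pheno["site"].value_counts()
    small = counts[counts < 2]
    if len(small):
        raise DataError(f"sites with fewer than 2 subjects: {small.index.tolist()}")

    sites = sorted(counts.index.tolist())
    site_idx = pheno["site"].map({s: i for i, s in enumerate(sites)}).to_numpy()
    age = pheno["age"].to_numpy(dtype=float)
    age_center = float(age.mean())
    sex, sex_coding = _encode_sex(pheno["sex"])

    n, S = len(pheno), len(sites)
    D = np.zeros((n, S + 2))
    D[np.arange(n), site_idx] = 1.0
    D[:, S] = age - age_center
    D[:, S + 1] = sex
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    resid = X - D @ beta
    hc_mean = None
    if "diagnosis" in pheno.columns:
        hc = (pheno["diagnosis"] == "HC").to_numpy()
        if hc.any():
            hc_mean = resid[hc].mean(axis=0)
    model = ConfoundModel(
        site_list=sites,
        site_offsets=beta[:S],
        beta_age=beta[S],
        beta_sex=beta[S + 1],
        age_center=age_center,
        sex_coding=sex_coding,
        hc_residual_mean=hc_mean,
    )
    if return_residuals:
        return model, resid
    return model


def apply_confound_model(
    model: ConfoundModel,
    X: np.ndarray,
    pheno: pd.DataFrame,
    unknown_site: str = "error",
) -> np.ndarray:
    """Residualize features with a fitted model: x - predicted(site, age, sex).

    ``unknown_site`` controls subjects whose site has no training dummy:
    ``"error"`` (default) refuses and points at the calibration path;
    ``"mean"`` subtracts the mean of the training site offsets instead — the
    no-calibration transfer condition, in which any true site shift of the
    new site remains in the features.
    """
    X = np.asarray(X, dtype=float)
    _check_pheno(pheno)
    known = pheno["site"].isin(model.site_list).to_numpy()
    if known.all():
        return X - model.predict(pheno)
    if unknown_site == "error":
        unseen = sorted(set(pheno.loc[~known, "site"]))
        raise UsageError(
            f"sites {unseen} not in the trained model; use calibrate_new_site"
        )
    if unknown_site != "mean":
        raise UsageError("unknown_site must be 'error' or 'mean'")
    resid = np.empty_like(X)
    if known.any():
        resid[known] = X[known] - model.predict(pheno.loc[known])
    mean_offset = model.site_offsets.mean(axis=0)
    resid[~known] = model.covariate_adjust(X[~known], pheno.loc[~known]) - mean_offset
    return resid


def calibrate_new_site(
    model: ConfoundModel,
    X_cal: np.ndarray,
    pheno_cal: pd.DataFrame,
    method: str = "offset",
    X_train: np.ndarray | None = None,
    pheno_train: pd.DataFrame | None = None,
) -> SiteCalibration:
    """Estimate a new site's per-edge offset from its calibration healthy controls.

    ``method="offset"`` (default) freezes the training age/sex coefficients
    and takes the calibration-control mean of the covariate-adjusted
    features; it cannot perturb the trained classifier's feature geometry.
    ``method="refit"`` re-estimates the full regression on training plus
    calibration subjects with an added dummy for the new site (requires
    ``X_train``/``pheno_train``); with balanced covariates both agree.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    _check_pheno(pheno_cal, required=("site", "age", "sex", "diagnosis"))
    if not (pheno_cal["diagnosis"] == "HC").all():
        raise UsageError("calibration subjects must all be healthy controls")
    sites = set(pheno_cal["site"])
    if len(sites) != 1:
        raise UsageError(f"calibration subjects span multiple sites: {sorted(sites)}")
    site = sites.pop()
    if site in model.site_list:
        raise UsageError(f"site '{site}' is already in the trained model")
    ids = pheno_cal["id"].tolist() if "id" in pheno_cal.columns else list(range(len(pheno_cal)))

    # anchor the calibration controls to the training controls' residual mean:
    # when the training fit pooled patients and controls, zero is not where
    # training controls sit, and anchoring there would shift the new site's
    # subjects relative to the decision boundary by the absorbed effect.
    hc_anchor = model.hc_residual_mean if model.hc_residual_mean is not None else 0.0
    if method == "offset":
        adj = model.covariate_adjust(X_cal, pheno_cal)
        offset = adj.mean(axis=0) - hc_anchor
    elif method == "refit":
        if X_train is None or pheno_train is None:
            raise UsageError("method='refit' requires X_train and pheno_train")
        X_all = np.vstack([np.asarray(X_train, dtype=float), X_cal])
        pheno_all = pd.concat([pheno_train, pheno_cal], ignore_index=True)
        refit = fit_confound_model(X_all, pheno_all)
        offset = refit.site_offsets[refit.site_list.index(site)]
        # express the offset on the training model's age centering
        offset = offset + model.beta_age * (model.age_center - refit.age_center) - hc_anchor
    else:
        raise UsageError("method must be 'offset' or 'refit'")
    return SiteCalibration(
        site_name=site, offset=offset, n_calibration=len(pheno_cal), calibration_ids=ids
    )


def apply_calibration(
    model: ConfoundModel,
    cal: SiteCalibration,
    X: np.ndarray,
    pheno: pd.DataFrame,
    allow_calibration_overlap: bool = False,
) -> np.ndarray:
    """Residualize new-site subjects: x - beta_age*age_c - beta_sex*sex - offset.

    Refuses subjects that were used for the calibration itself (leakage)
    unless ``allow_calibration_overlap`` is set, in which case a warning is
    logged.
    """
    X = np.asarray(X, dtype=float)
    _check_pheno(pheno)
    wrong = sorted(set(pheno["site"]) - {cal.site_name})
    if wrong:
        raise UsageError(f"subjects from sites {wrong} do not belong to calibration '{cal.site_name}'")
    if "id" in pheno.columns:
        overlap = sorted(set(pheno["id"]) & set(cal.calibration_ids))
        if overlap:
            if not allow_calibration_overlap:
                raise LeakageError(
                    f"subjects {overlap} were used for calibration; refusing to score them"
                )
            logger.warning("scoring calibration subjects %s (leakage override)", overlap)
    return model.covariate_adjust(X, pheno) - cal.offset[None, :]
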