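"""Leakage-free evaluation protocols for diagnostic connectivity classifiers.

Every protocol refits the entire training side — confound regression,
rank-sum feature selection, and (when a Bayesian-optimization budget is
given) hyperparameter search — inside each training split, and a runtime
leakage guard asserts that no test subject's identifier ever reaches the
fitting path.  Protocols:

* :func:`run_loocv` — strict leave-one-subject-out.
* :func:`run_kfold` — stratified 9-fold outer loop (diagnosis x sex x site
  strata), hyperparameters tuned by 8-fold inner cross-validation.
* :func:`run_loso` — leave-one-site-out; the held-out site has no dummy in
  the confound model, so its features are residualized without a site term
  (mean training offset), exposing any uncorrected site shift.
* :func:`run_independent_site` — train on all training sites, then
  repeatedly (default 100x) draw calibration healthy controls from the new
  site, estimate its offset, and score the remaining, class-balanced
  subjects; reports mean +/- SD across repeats plus the uncalibrated
  baseline.
* :func:`permutation_test` — full-pipeline label-permutation null with the
  add-one p-value (1 + #{null >= observed}) / (n_permutations + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from connharm.errors import DataError, LeakageError, UsageError
from connharm.harmonization import (
    apply_calibration,
    apply_confound_model,
    calibrate_new_site,
    fit_confound_model,
)
from connharm.modeling import (
    optimize_hyperparameters,
    ranksum_select,
    train_classifier,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- folds & metrics


@dataclass
class FoldPlan:
    """Stratified partition of subjects into k folds."""

    k: int
    assignments: dict  # subject id -> fold
    keys: tuple

    def fold_ids(self, fold: int) -> list:
        return [sid for sid, f in self.assignments.items() if f == fold]


def stratified_folds(pheno: pd.DataFrame, k: int, keys=("diagnosis", "sex", "site"), rng=None) -> FoldPlan:
    """Assign subjects to k folds keeping every key-combination stratum balanced.

    Within each stratum subjects are shuffled and dealt round-robin starting
    from a rotating fold offset, so per-stratum fold counts differ by at most
    one and overall fold sizes stay even.
    """
    if k < 2:
        raise UsageError("k must be >= 2")
    if k > len(pheno):
        raise UsageError(f"k={k} exceeds the {len(pheno)} subjects")
    bad = [key for key in keys if key not in pheno.columns]
    if bad:
        raise DataError(f"stratification keys missing from phenotypes: {bad}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    assignments = {}
    offset = 0
    strata = pheno.groupby(list(keys), sort=True, observed=True)
    for _, grp in strata:
        ids = grp["id"].tolist()
        order = rng.permutation(len(ids))
        for pos, idx in enumerate(order):
            assignments[ids[idx]] = (offset + pos) % k
        offset = (offset + len(ids)) % k
    return FoldPlan(k=k, assignments=assignments, keys=tuple(keys))


def compute_metrics(y_true, y_pred, scores=None) -> dict:
    """Accuracy, sensitivity (patient detection), specificity (control detection), AUC.

    Labels are 0 = healthy control, 1 = patient.  With a single class in
    ``y_true`` the undefined metrics are NaN and flagged under "undefined".
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) == 0:
        raise UsageError("empty input")
    if len(y_true) != len(y_pred):
        raise UsageError("length mismatch")
    out = {"accuracy": float(np.mean(y_true == y_pred))}
    undefined = []
    n_pat = int((y_true == 1).sum())
    n_hc = int((y_true == 0).sum())
    out["sensitivity"] = float((y_pred[y_true == 1] == 1).mean()) if n_pat else float("nan")
    out["specificity"] = float((y_pred[y_true == 0] == 0).mean()) if n_hc else float("nan")
    if not n_pat:
        undefined.append("sensitivity")
    if not n_hc:
        undefined.append("specificity")
    if scores is not None and n_pat and n_hc:
        scores = np.asarray(scores, dtype=float)
        ranks = stats.rankdata(scores)
        auc = (ranks[y_true == 1].sum() - n_pat * (n_pat + 1) / 2) / (n_pat * n_hc)
        out["auc"] = float(auc)
    elif scores is not None:
        out["auc"] = float("nan")
        undefined.append("auc")
    if undefined:
        out["undefined"] = undefined
    return out


# ---------------------------------------------------------------- reports


@dataclass
class EvalReport:
    """Metrics for one evaluation protocol, with per-unit detail."""

    protocol: str
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None = None
    detail: list = field(default_factory=list)  # per fold / site / repeat dicts
    summary_sd: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "detail": self.detail,
            "summary_sd": self.summary_sd,
            "config": self.config,
        }


@dataclass
class PermutationResult:
    """Observed accuracy against a label-permutation null distribution."""

    observed_accuracy: float
    null_accuracies: list
    n_permutations: int

    @property
    def p_value(self) -> float:
        null = np.asarray(self.null_accuracies)
        return float((1 + np.sum(null >= self.observed_accuracy)) / (self.n_permutations + 1))


# ---------------------------------------------------------------- pipeline plumbing


def _leakage_guard(train_ids, test_ids) -> None:
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise LeakageError(f"subjects in both train and test: {sorted(overlap)}")


def _fit_pipeline(X_tr, pheno_tr, y_tr, algorithm, alpha, bo_budget, rng, seed):
    """Confound fit -> residualize -> rank-sum select -> (optional BO) -> train."""
    model, resid = fit_confound_model(X_tr, pheno_tr, return_residuals=True)
    sel = ranksum_select(resid, y_tr, alpha)
    mask = sel.mask
    if not mask.any():
        # nothing survives the screen: keep the single smallest-p edge
        mask = np.zeros_like(mask)
        mask[int(np.argmin(sel.p_values))] = True
        logger.info("rank-sum screen selected nothing; keeping the smallest-p edge")
    Xs = resid[:, mask]
    if bo_budget >= 5 and algorithm != "slr":
        hp, _ = optimize_hyperparameters(algorithm, Xs, y_tr, budget=bo_budget, rng=rng)
    else:
        hp = None
    clf = train_classifier(algorithm, Xs, y_tr, hyperparams=hp, feature_mask=mask, seed=seed)
    return model, mask, clf


def _predict(model, clf, X_te, pheno_te, unknown_site="error", calibration=None):
    if calibration is not None:
        resid = apply_calibration(model, calibration, X_te, pheno_te)
    else:
        resid = apply_confound_model(model, X_te, pheno_te, unknown_site=unknown_site)
    return clf.predict(resid), clf.decision_scores(resid)


def _labels(pheno: pd.DataFrame) -> np.ndarray:
    return (pheno["diagnosis"].to_numpy() == "MDD").astype(int)


def _cohort_arrays(dataset):
    """Accept a SyntheticCohort or a (features, phenotypes) pair."""
    if hasattr(dataset, "phenotypes"):
        return np.asarray(dataset.features, dtype=float), dataset.phenotypes
    X, pheno = dataset
    return np.asarray(X, dtype=float), pheno


# ---------------------------------------------------------------- protocols


def run_loocv(dataset, algorithm="svm", alpha=0.05, bo_budget=0, rng=None) -> EvalReport:
    """Strict leave-one-subject-out: the whole pipeline refits for every subject."""
    X, pheno = _cohort_arrays(dataset)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    seed = int(rng.integers(2**31 - 1))
    y = _labels(pheno)
    preds = np.empty(len(y), dtype=int)
    scores = np.empty(len(y), dtype=float)
    detail = []
    for i in range(len(y)):
        tr = np.setdiff1d(np.arange(len(y)), [i])
        _leakage_guard(pheno["id"].iloc[tr], [pheno["id"].iloc[i]])
        model, mask, clf = _fit_pipeline(
            X[tr], pheno.iloc[tr], y[tr], algorithm, alpha, bo_budget, rng, seed
        )
        p, s = _predict(model, clf, X[[i]], pheno.iloc[[i]])
        preds[i], scores[i] = int(p[0]), float(s[0])
        detail.append({"id": pheno["id"].iloc[i], "true": int(y[i]), "pred": int(preds[i])})
    m = compute_metrics(y, preds, scores)
    return EvalReport(
        protocol="loocv",
        accuracy=m["accuracy"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        auc=m.get("auc"),
        detail=detail,
        config={"algorithm": algorithm, "alpha": alpha, "bo_budget": bo_budget, "seed": seed},
    )


def run_kfold(dataset, algorithm="svm", alpha=0.05, bo_budget=0, k=9, rng=None) -> EvalReport:
    """Stratified k-fold outer loop (default 9) with 8-fold inner hyperparameter CV."""
    X, pheno = _cohort_arrays(dataset)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    seed = int(rng.integers(2**31 - 1))
    y = _labels(pheno)
    keys = [key for key in ("diagnosis", "sex", "site") if key in pheno.columns]
    plan = stratified_folds(pheno, k, keys=tuple(keys), rng=rng)
    fold_of = pheno["id"].map(plan.assignments).to_numpy()
    preds = np.empty(len(y), dtype=int)
    scores = np.empty(len(y), dtype=float)
    detail = []
    for f in range(k):
        te = np.flatnonzero(fold_of == f)
        tr = np.flatnonzero(fold_of != f)
        if len(te) == 0:
            continue
        _leakage_guard(pheno["id"].iloc[tr], pheno["id"].iloc[te])
        model, mask, clf = _fit_pipeline(
            X[tr], pheno.iloc[tr], y[tr], algorithm, alpha, bo_budget, rng, seed
        )
        p, s = _predict(model, clf, X[te], pheno.iloc[te])
        preds[te], scores[te] = p, s
        fm = compute_metrics(y[te], p, s)
        detail.append({"fold": f, "n": int(len(te)), **fm})
    m = compute_metrics(y, preds, scores)
    return EvalReport(
        protocol=f"{k}fold",
        accuracy=m["accuracy"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        auc=m.get("auc"),
        detail=detail,
        config={"algorithm": algorithm, "alpha": alpha, "bo_budget": bo_budget, "k": k, "seed": seed},
    )


def run_loso(dataset, algorithm="svm", alpha=0.05, bo_budget=0, rng=None) -> list[EvalReport]:
    """Leave-one-site-out: train on the other sites, test the held-out site raw.

    The held-out site has no dummy in the confound model, so its features are
    residualized with the mean training-site offset — the uncalibrated
    transfer condition.  One report per site; per-site AUC included.  A
    held-out site with a single diagnostic class gets NaN for the undefined
    metrics rather than fabricated values.
    """
    X, pheno = _cohort_arrays(dataset)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sites = sorted(pheno["site"].unique())
    if len(sites) < 2:
        raise UsageError("leave-one-site-out needs at least 2 sites")
    y = _labels(pheno)
    reports = []
    for site in sites:
        seed = int(rng.integers(2**31 - 1))
        te = np.flatnonzero((pheno["site"] == site).to_numpy())
        tr = np.flatnonzero((pheno["site"] != site).to_numpy())
        _leakage_guard(pheno["id"].iloc[tr], pheno["id"].iloc[te])
        model, mask, clf = _fit_pipeline(
            X[tr], pheno.iloc[tr], y[tr], algorithm, alpha, bo_budget, rng, seed
        )
        p, s = _predict(model, clf, X[te], pheno.iloc[te], unknown_site="mean")
        m = compute_metrics(y[te], p, s)
        reports.append(
            EvalReport(
                protocol="loso",
                accuracy=m["accuracy"],
                sensitivity=m["sensitivity"],
                specificity=m["specificity"],
                auc=m.get("auc"),
                detail=[{"site": site, "n": int(len(te)), **m}],
                config={"algorithm": algorithm, "alpha": alpha, "bo_budget": bo_budget,
                        "held_out_site": site, "seed": seed},
            )
        )
    return reports


def run_independent_site(
    train_dataset,
    test_site_dataset,
    algorithm="svm",
    alpha=0.05,
    bo_budget=0,
    n_repeats=100,
    n_calibration=None,
    rng=None,
) -> EvalReport:
    """Independent-site transfer with repeated healthy-control calibration.

    The classifier is trained once on the training sites.  Each repeat draws
    ``n_calibration`` healthy controls from the new site (default
    n_HC - n_MDD, so the remaining test set is class-balanced), estimates the
    site offset from them, and scores the remaining controls plus all
    patients.  The report carries the across-repeat mean of each metric, the
    SD under ``summary_sd``, per-repeat detail, and the uncalibrated baseline
    (full site, mean-training-offset residualization) under
    ``config["uncalibrated"]``.
    """
    X_tr, pheno_tr = _cohort_arrays(train_dataset)
    X_te, pheno_te = _cohort_arrays(test_site_dataset)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    seed = int(rng.integers(2**31 - 1))
    test_sites = set(pheno_te["site"])
    if len(test_sites) != 1:
        raise UsageError("test dataset must come from exactly one site")
    site = test_sites.pop()
    if site in set(pheno_tr["site"]):
        raise UsageError(f"test site '{site}' appears in the training data")
    if n_repeats < 1:
        raise UsageError("n_repeats must be >= 1")
    _leakage_guard(pheno_tr["id"], pheno_te["id"])

    y_tr = _labels(pheno_tr)
    y_te = _labels(pheno_te)
    hc_idx = np.flatnonzero(y_te == 0)
    mdd_idx = np.flatnonzero(y_te == 1)
    if n_calibration is None:
        n_calibration = len(hc_idx) - len(mdd_idx)
        if n_calibration < 1:
            raise UsageError(
                "test site has no healthy-control surplus; pass n_calibration explicitly"
            )
    if n_calibration >= len(hc_idx):
        raise UsageError("n_calibration must leave at least one healthy control for testing")

    model, mask, clf = _fit_pipeline(
        X_tr, pheno_tr, y_tr, algorithm, alpha, bo_budget, rng, seed
    )

    # uncalibrated baseline on the full site (no site term available)
    p0, s0 = _predict(model, clf, X_te, pheno_te, unknown_site="mean")
    baseline = compute_metrics(y_te, p0, s0)

    detail = []
    n_test_hc = len(hc_idx) - n_calibration
    for rep in range(n_repeats):
        cal = rng.choice(hc_idx, size=n_calibration, replace=False)
        rest_hc = np.setdiff1d(hc_idx, cal)
        # class-balanced test set: as many controls as patients where possible
        n_take = min(len(rest_hc), len(mdd_idx))
        test_hc = rng.choice(rest_hc, size=n_take, replace=False) if len(rest_hc) > n_take else rest_hc
        te = np.concatenate([test_hc, mdd_idx])
        calibration = calibrate_new_site(model, X_te[cal], pheno_te.iloc[cal])
        p, s = _predict(model, clf, X_te[te], pheno_te.iloc[te], calibration=calibration)
        m = compute_metrics(y_te[te], p, s)
        detail.append({"repeat": rep, "n_test": int(len(te)), **m})

    def agg(key):
        vals = np.array([d[key] for d in detail], dtype=float)
        return float(np.nanmean(vals)), float(np.nanstd(vals))

    acc, acc_sd = agg("accuracy")
    sen, sen_sd = agg("sensitivity")
    spe, spe_sd = agg("specificity")
    auc, auc_sd = agg("auc") if "auc" in detail[0] else (None, None)
    return EvalReport(
        protocol="independent_site",
        accuracy=acc,
        sensitivity=sen,
        specificity=spe,
        auc=auc,
        detail=detail,
        summary_sd={"accuracy": acc_sd, "sensitivity": sen_sd, "specificity": spe_sd,
                    **({"auc": auc_sd} if auc_sd is not None else {})},
        config={
            "algorithm": algorithm, "alpha": alpha, "bo_budget": bo_budget,
            "site": site, "n_repeats": n_repeats, "n_calibration": int(n_calibration),
            "n_test_hc": int(n_test_hc), "seed": seed, "uncalibrated": baseline,
        },
    )


def permutation_test(
    dataset, protocol="kfold", algorithm="svm", n_permutations=500, rng=None, **protocol_kwargs
) -> PermutationResult:
    """Full-pipeline label-permutation test of classification performance.

    Diagnostic labels are permuted before any training-side computation —
    selection, confound regression and fitting are redone per permutation —
    so the null reflects the entire pipeline.  ``protocol`` is "kfold" or
    "loocv".
    """
    if n_permutations < 1:
        raise UsageError("n_permutations must be >= 1")
    runner = {"kfold": run_kfold, "loocv": run_loocv}.get(protocol)
    if runner is None:
        raise UsageError(f"unknown protocol '{protocol}'")
    X, pheno = _cohort_arrays(dataset)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    observed = runner((X, pheno), algorithm=algorithm, rng=rng, **protocol_kwargs).accuracy
    null = []
    dx = pheno["diagnosis"].to_numpy()
    for _ in range(n_permutations):
        perm = pheno.copy()
        perm["diagnosis"] = dx[rng.permutation(len(dx))]
        null.append(runner((X, perm), algorithm=algorithm, rng=rng, **protocol_kwargs).accuracy)
    return PermutationResult(
        observed_accuracy=observed, null_accuracies=null, n_permutations=n_permutations
    )


# ---------------------------------------------------------------- subgroups & diagnostics


def filter_subgroup(pheno: pd.DataFrame, subtype: str = "all"):
    """Restrict the patient group to a clinical subtype.

    ``subtype="melancholic"`` returns ``(subgroup_index, transfer_index)``:
    the subgroup keeps all healthy controls plus melancholic patients; the
    transfer set holds the non-melancholic patients, used to ask whether a
    subgroup-trained classifier still detects less typical patients.
    ``subtype="all"`` returns all rows and an empty transfer set.
    """
    if subtype == "all":
        return np.arange(len(pheno)), np.array([], dtype=int)
    if subtype != "melancholic":
        raise UsageError(f"unknown subtype '{subtype}'")
    if "melancholic" not in pheno.columns:
        raise DataError("phenotype table has no 'melancholic' column")
    is_mdd = (pheno["diagnosis"] == "MDD").to_numpy()
    mel = pheno["melancholic"].to_numpy().astype(bool)
    if not (is_mdd & mel).any():
        raise DataError("no melancholic patients in the cohort")
    keep = np.flatnonzero(~is_mdd | mel)
    transfer = np.flatnonzero(is_mdd & ~mel)
    return keep, transfer


def interaction_diagnostics(X, pheno: pd.DataFrame, n_bins: int = 20) -> dict:
    """Per-edge F-test of site x age and site x sex interactions, pooled into a GOF test.

    For every edge the additive model [site dummies, centered age, sex] is
    compared with the full model adding site x age and site x sex interaction
    columns; the p-values of the block F-test are binned (equal width) and a
    chi-square goodness-of-fit statistic against uniformity (n_bins - 1
    degrees of freedom) summarizes whether interactions are ignorable.
    """
    X = np.asarray(X, dtype=float)
    sites = sorted(pheno["site"].unique())
    if len(sites) < 2:
        raise UsageError("interaction diagnostics need at least 2 sites")
    site_idx = pheno["site"].map({s: i for i, s in enumerate(sites)}).to_numpy()
    n, S = len(pheno), len(sites)
    age_c = pheno["age"].to_numpy(dtype=float)
    age_c = age_c - age_c.mean()
    from connharm.harmonization import _encode_sex

    sex, _ = _encode_sex(pheno["sex"])
    dummies = np.zeros((n, S))
    dummies[np.arange(n), site_idx] = 1.0
    D0 = np.column_stack([dummies, age_c, sex])
    inter = np.column_stack(
        [dummies[:, 1:] * age_c[:, None], dummies[:, 1:] * sex[:, None]]
    )
    D1 = np.column_stack([D0, inter])
    q = inter.shape[1]
    df_resid = n - D1.shape[1]
    if df_resid < 1:
        raise DataError("insufficient residual degrees of freedom for the interaction model")

    def rss(D):
        beta, *_ = np.linalg.lstsq(D, X, rcond=None)
        r = X - D @ beta
        return np.sum(r**2, axis=0)

    rss0, rss1 = rss(D0), rss(D1)
    F = ((rss0 - rss1) / q) / np.clip(rss1 / df_resid, 1e-300, None)
    p = stats.f.sf(F, q, df_resid)
    counts, _ = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    expected = len(p) / n_bins
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    gof_p = float(stats.chi2.sf(chi2, n_bins - 1))
    return {
        "p_values": p,
        "histogram": counts,
        "n_bins": n_bins,
        "chi2": chi2,
        "gof_p": gof_p,
        "df": n_bins - 1,
    }
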