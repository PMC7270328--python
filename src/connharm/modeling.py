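"""Feature selection, classifiers, and Bayesian hyperparameter optimization.

Feature screening is a per-edge two-sided Wilcoxon rank-sum test on the
training data only; edges with p below the threshold (0.05 by default) enter
the classifier.  Four classifier families are supported: support vector
machine, random forest, AdaBoost, and sparse logistic regression (SLR).
SLR is automatic-relevance-determination (ARD) logistic regression — a
Bayesian logistic model with an independent Gaussian prior per weight whose
precisions are optimized by evidence maximization; weights whose precision
diverges are pruned, so the model selects its own features and needs no
tuned hyperparameters.

For the other three families, hyperparameters are chosen by Bayesian
optimization: a Gaussian-process surrogate over the (log-scaled,
one-hot-encoded) search space, maximizing inner-cross-validated accuracy via
the Expected Improvement acquisition function.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from connharm.errors import UsageError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- selection


@dataclass
class SelectionResult:
    """Per-edge rank-sum p-values and the resulting selection mask (p < alpha)."""

    p_values: np.ndarray
    alpha: float
    mask: np.ndarray

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def ranksum_select(X: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> SelectionResult:
    """Two-sided Wilcoxon rank-sum screen of every feature, on training data only.

    Uses the exact null distribution when both groups have at most 10
    subjects and the normal approximation with tie and continuity correction
    otherwise.  An edge is selected when p < alpha.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not 0 < alpha < 1:
        raise UsageError("alpha must be in (0, 1)")
    classes = np.unique(y)
    if len(classes) != 2:
        raise UsageError(f"need exactly two classes, got {classes.tolist()}")
    g0, g1 = X[y == classes[0]], X[y == classes[1]]
    method = "exact" if max(len(g0), len(g1)) <= 10 else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ties under exact method fall back internally
        res = stats.mannwhitneyu(g0, g1, axis=0, alternative="two-sided", method=method)
    p = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    return SelectionResult(p_values=p, alpha=alpha, mask=p < alpha)


# ---------------------------------------------------------------- classifiers


@dataclass
class HyperparamSpace:
    """Search space for one classifier family.

    ``dims`` is a list of (name, kind, spec): kind "log" or "linear" with
    spec (low, high), or kind "cat" with spec a tuple of choices.
    """

    algorithm: str
    dims: list = field(default_factory=list)

    @classmethod
    def default(cls, algorithm: str, n_samples: int) -> "HyperparamSpace":
        n = max(int(n_samples), 4)
        if algorithm == "svm":
            dims = [
                ("box_constraint", "log", (1e-3, 1e3)),
                ("kernel_scale", "log", (1e-3, 1e3)),
                ("kernel", "cat", ("gaussian", "linear", "polynomial")),
            ]
        elif algorithm == "random_forest":
            dims = [
                ("min_leaf_size", "linear", (1, max(n // 2, 2))),
                ("max_splits", "linear", (1, n - 1)),
                ("cycles", "linear", (10, 500)),
            ]
        elif algorithm == "adaboost":
            dims = [
                ("min_leaf_size", "linear", (1, max(n // 2, 2))),
                ("max_splits", "linear", (1, n - 1)),
                ("cycles", "linear", (10, 500)),
                ("learn_rate", "log", (1e-3, 1.0)),
            ]
        elif algorithm == "slr":
            dims = []  # hyperparameters are self-determined by evidence maximization
        else:
            raise UsageError(f"unknown algorithm '{algorithm}'")
        return cls(algorithm=algorithm, dims=dims)


DEFAULT_HYPERPARAMS = {
    "svm": {"box_constraint": 1.0, "kernel_scale": 1.0, "kernel": "linear"},
    "random_forest": {"min_leaf_size": 1, "max_splits": 50, "cycles": 100},
    "adaboost": {"min_leaf_size": 1, "max_splits": 1, "cycles": 100, "learn_rate": 0.1},
    "slr": {},
}


@dataclass
class TrainedClassifier:
    """A fitted diagnostic classifier plus the feature mask it was trained on.

    Labels are coded HC = 0, patient = 1.  ``decision_scores`` exposes a
    continuous value (larger = more patient-like) for ROC ranking.
    """

    algorithm: str
    hyperparams: dict
    estimator: object
    feature_mask: np.ndarray | None = None
    converged: bool = True

    def _subset(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.feature_mask is None:
            return X
        if X.shape[1] == int(self.feature_mask.sum()):
            return X
        if X.shape[1] == len(self.feature_mask):
            return X[:, self.feature_mask]
        raise UsageError(
            f"feature width {X.shape[1]} matches neither the mask length "
            f"{len(self.feature_mask)} nor the selected count {int(self.feature_mask.sum())}"
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._subset(X)), dtype=int)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        Xs = self._subset(X)
        est = self.estimator
        if hasattr(est, "decision_function"):
            return np.asarray(est.decision_function(Xs), dtype=float)
        proba = est.predict_proba(Xs)
        return np.asarray(proba[:, 1], dtype=float)


def _build_estimator(algorithm: str, hp: dict, seed: int):
    if algorithm == "svm":
        kernel = {"gaussian": "rbf", "linear": "linear", "polynomial": "poly"}[
            hp.get("kernel", "linear")
        ]
        scale = float(hp.get("kernel_scale", 1.0))
        return SVC(
            C=float(hp.get("box_constraint", 1.0)),
            kernel=kernel,
            gamma=1.0 / scale**2,  # MATLAB-style kernel scale divides the features
            degree=int(hp.get("poly_degree", 3)),
            random_state=seed,
        )
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(hp.get("cycles", 100)),
            min_samples_leaf=int(hp.get("min_leaf_size", 1)),
            max_leaf_nodes=int(hp.get("max_splits", 50)) + 1,
            bootstrap=bool(hp.get("bootstrap", True)),
            random_state=seed,
        )
    if algorithm == "adaboost":
        stump = DecisionTreeClassifier(
            min_samples_leaf=int(hp.get("min_leaf_size", 1)),
            max_leaf_nodes=int(hp.get("max_splits", 1)) + 1,
            random_state=seed,
        )
        return AdaBoostClassifier(
            estimator=stump,
            n_estimators=int(hp.get("cycles", 100)),
            learning_rate=float(hp.get("learn_rate", 0.1)),
            random_state=seed,
        )
    raise UsageError(f"unknown algorithm '{algorithm}'")


def train_classifier(
    algorithm: str,
    X: np.ndarray,
    y: np.ndarray,
    hyperparams: dict | None = None,
    feature_mask: np.ndarray | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit one classifier family on (already selected) training features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) != 2:
        raise UsageError("training labels must contain both classes")
    if algorithm == "slr":
        return fit_slr(X, y, feature_mask=feature_mask)
    hp = dict(DEFAULT_HYPERPARAMS.get(algorithm, {}))
    if hyperparams:
        hp.update(hyperparams)
    est = _build_estimator(algorithm, hp, seed)
    if feature_mask is not None:
        X = X[:, feature_mask] if X.shape[1] == len(feature_mask) else X
    est.fit(X, y)
    return TrainedClassifier(
        algorithm=algorithm, hyperparams=hp, estimator=est, feature_mask=feature_mask
    )


# ---------------------------------------------------------------- sparse logistic regression


class _ArdLogistic:
    """ARD logistic regression via Laplace approximation and MacKay updates.

    Each weight w_j has prior N(0, 1/alpha_j).  Alternates a Newton fit of
    the penalized log-likelihood with evidence-based precision updates
    alpha_j = gamma_j / w_j^2, gamma_j = 1 - alpha_j * Sigma_jj, pruning
    weights whose precision exceeds ``prune_threshold``.  The intercept
    carries a fixed, nearly flat prior and is never pruned.
    """

    def __init__(self, prune_threshold=1e8, max_iter=500, tol=1e-4, init_alpha=None):
        self.prune_threshold = prune_threshold
        self.max_iter = max_iter
        self.tol = tol
        self.init_alpha = init_alpha
        self.converged_ = False

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, d = X.shape
        Phi = np.column_stack([np.ones(n), X])
        active = np.ones(d + 1, dtype=bool)
        # starting from strong shrinkage approximates the sequential "start
        # empty" construction: only features the evidence supports escape it
        alpha = np.full(d + 1, float(n) if self.init_alpha is None else self.init_alpha)
        alpha[0] = 1e-6  # effectively flat prior on the intercept
        w = np.zeros(d + 1)
        prev_evidence = -np.inf
        for _ in range(self.max_iter):
            A = Phi[:, active]
            a = alpha[active]
            wa = w[active]
            # inner Newton (IRLS) for the MAP weights at fixed precisions
            for _ in range(50):
                eta = A @ wa
                mu = expit(eta)
                g = A.T @ (y - mu) - a * wa
                s = np.clip(mu * (1 - mu), 1e-10, None)
                H = (A.T * s) @ A + np.diag(a)
                step = np.linalg.solve(H, g)
                wa = wa + step
                if np.max(np.abs(step)) < 1e-8:
                    break
            eta = A @ wa
            mu = expit(eta)
            s = np.clip(mu * (1 - mu), 1e-10, None)
            H = (A.T * s) @ A + np.diag(a)
            Sigma = np.linalg.inv(H)
            gamma = 1.0 - a * np.diag(Sigma)
            # log marginal likelihood (Laplace)
            ll = np.sum(y * np.log(np.clip(mu, 1e-12, 1)) + (1 - y) * np.log(np.clip(1 - mu, 1e-12, 1)))
            sign, logdet = np.linalg.slogdet(H)
            evidence = (
                ll
                - 0.5 * np.sum(a * wa**2)
                + 0.5 * np.sum(np.log(a))
                - 0.5 * logdet
            )
            w[:] = 0.0
            w[active] = wa
            # MacKay precision update for all but the intercept
            new_a = np.where(wa**2 > 1e-300, np.clip(gamma, 1e-12, None) / np.clip(wa**2, 1e-300, None), np.inf)
            idx = np.flatnonzero(active)
            alpha_change = 0.0
            for k, j in enumerate(idx):
                if j == 0:
                    continue
                na = min(new_a[k], 10 * self.prune_threshold)
                alpha_change = max(alpha_change, abs(np.log(na) - np.log(alpha[j])))
                alpha[j] = na
            newly_pruned = (alpha > self.prune_threshold) & active
            newly_pruned[0] = False
            if newly_pruned.any():
                active &= ~newly_pruned
                w[newly_pruned] = 0.0
            # converge on the evidence, but only once the precisions stop moving:
            # evidence flattens long before slowly-diverging precisions prune out
            if (
                prev_evidence > -np.inf
                and abs(evidence - prev_evidence) < self.tol * (abs(prev_evidence) + 1e-12)
                and alpha_change < 1e-3
            ):
                self.converged_ = True
                break
            prev_evidence = evidence
        self.coef_ = w[1:]
        self.intercept_ = w[0]
        self.active_features_ = active[1:]
        if not self.converged_:
            warnings.warn("ARD logistic regression did not converge", RuntimeWarning, stacklevel=2)
        return self

    def decision_function(self, X):
        return self.intercept_ + np.asarray(X, dtype=float) @ self.coef_

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


def fit_slr(
    X: np.ndarray, y: np.ndarray, feature_mask: np.ndarray | None = None
) -> TrainedClassifier:
    """Sparse logistic regression: ARD prunes its own features, no tuning needed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) != 2:
        raise UsageError("training labels must contain both classes")
    if feature_mask is not None and X.shape[1] == len(feature_mask):
        X = X[:, feature_mask]
    est = _ArdLogistic().fit(X, y)
    return TrainedClassifier(
        algorithm="slr",
        hyperparams={},
        estimator=est,
        feature_mask=feature_mask,
        converged=est.converged_,
    )


# ---------------------------------------------------------------- Bayesian optimization


def _encode_point(params: dict, space: HyperparamSpace) -> np.ndarray:
    """Map a parameter dict to [0,1]^m (log/linear scaling, one-hot categoricals)."""
    out = []
    for name, kind, spec in space.dims:
        v = params[name]
        if kind == "cat":
            out.extend(1.0 if v == c else 0.0 for c in spec)
        elif kind == "log":
            lo, hi = np.log(spec[0]), np.log(spec[1])
            out.append((np.log(v) - lo) / (hi - lo))
        else:
            lo, hi = spec
            out.append((v - lo) / (hi - lo))
    return np.array(out)


def _sample_point(space: HyperparamSpace, rng: np.random.Generator) -> dict:
    params = {}
    for name, kind, spec in space.dims:
        if kind == "cat":
            params[name] = spec[rng.integers(len(spec))]
        elif kind == "log":
            params[name] = float(np.exp(rng.uniform(np.log(spec[0]), np.log(spec[1]))))
        else:
            lo, hi = spec
            if isinstance(lo, int) and isinstance(hi, int):
                params[name] = int(rng.integers(lo, hi + 1))
            else:
                params[name] = float(rng.uniform(lo, hi))
    return params


def _cv_accuracy(algorithm, X, y, hp, k, seed) -> float:
    """Inner stratified k-fold accuracy at one hyperparameter setting."""
    _, counts = np.unique(y, return_counts=True)
    k_eff = int(min(k, counts.min()))
    if k_eff < 2:
        raise UsageError("too few subjects per class for inner cross-validation")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        try:
            clf = train_classifier(algorithm, X[tr], y[tr], hyperparams=hp, seed=seed)
            correct += int((clf.predict(X[te]) == y[te]).sum())
        except ValueError:
            # a hyperparameter setting the estimator cannot fit scores zero
            pass
    return correct / len(y)


def optimize_hyperparameters(
    algorithm: str,
    X: np.ndarray,
    y: np.ndarray,
    space: HyperparamSpace | None = None,
    budget: int = 30,
    rng=None,
    inner_k: int = 8,
    n_initial: int = 8,
):
    """Gaussian-process Bayesian optimization of inner-CV accuracy.

    Random initial design, then a Matern-5/2 GP surrogate on the normalized
    encoded space; each subsequent point maximizes Expected Improvement over
    a random candidate set.  Returns ``(best_params, trace)`` where trace is
    the list of (params, accuracy) in evaluation order.  With ``budget < 5``
    the default hyperparameters are returned with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if space is None:
        space = HyperparamSpace.default(algorithm, len(y))
    if not space.dims:  # slr: nothing to optimize
        return dict(DEFAULT_HYPERPARAMS.get(algorithm, {})), []
    if budget < 5:
        warnings.warn(
            "budget < 5: falling back to default hyperparameters", RuntimeWarning, stacklevel=2
        )
        return dict(DEFAULT_HYPERPARAMS[algorithm]), []

    seed = int(rng.integers(2**31 - 1))
    trace = []
    encoded = []
    accs = []

    def evaluate(params):
        acc = _cv_accuracy(algorithm, X, y, params, inner_k, seed)
        trace.append((params, acc))
        encoded.append(_encode_point(params, space))
        accs.append(acc)

    n_init = min(n_initial, budget)
    for _ in range(n_init):
        evaluate(_sample_point(space, rng))

    kernel = ConstantKernel(1.0) * Matern(length_scale=0.5, nu=2.5) + WhiteKernel(1e-4)
    for _ in range(budget - n_init):
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=seed, alpha=1e-8
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.array(encoded), np.array(accs))
        cands = [_sample_point(space, rng) for _ in range(256)]
        Z = np.array([_encode_point(c, space) for c in cands])
        mu, sd = gp.predict(Z, return_std=True)
        best = max(accs)
        sd = np.clip(sd, 1e-12, None)
        imp = mu - best
        zsc = imp / sd
        ei = imp * stats.norm.cdf(zsc) + sd * stats.norm.pdf(zsc)
        evaluate(cands[int(np.argmax(ei))])

    best_idx = int(np.argmax(accs))
    return trace[best_idx][0], trace
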