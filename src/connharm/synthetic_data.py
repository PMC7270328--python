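"""Synthetic multi-site cohorts with known ground truth.

No clinical functional-connectivity dataset ships with this package, so every
downstream stage (harmonization, calibration, selection, classification,
evaluation protocols) is exercised on simulated cohorts whose generative
parameters — per-site feature offsets, covariate slopes, the sparse set of
edges carrying a diagnosis effect — are recorded exactly as sampled.

The feature-mode generative model for subject s at edge e is

    z_se = mu_e + beta_age_e * (age_s - age0) + beta_sex_e * sex_s
           + delta_{site(s), e}
           + d_s * 1{s is a patient} * 1{e in affected set}
           + eps_se,        eps_se ~ N(0, noise_sd^2)

with ages uniform on [20, 75] (the cohort age range the method targets),
balanced sex, fixed (not random) per-site offsets delta — the same additive
fixed-effect structure the harmonization regression removes.  Patients
flagged melancholic may carry a larger effect size than the remaining
patients, emulating a biologically more homogeneous subgroup.

Time-series mode realizes the designed edge correlations as latent
multivariate-normal ROI series with AR(1) temporal structure plus synthetic
nuisance traces, so the connectivity pipeline can be exercised end to end.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from connharm.connectivity import EdgeIndex, RoiTimeSeries, edge_index
from connharm.errors import ConfigurationError

AGE_RANGE = (20.0, 75.0)


@dataclass
class SyntheticConfig:
    """Generative parameters of a synthetic multi-site cohort.

    Defaults describe a moderate scenario: four acquisition sites, sparse
    diagnosis effects of standardized size ``effect_size`` on a random 2% of
    edges, additive per-site offsets with SD ``site_offset_sd`` (in units of
    the subject-level noise SD), and weak age/sex slopes.
    """

    n_sites: int = 4
    n_hc_per_site: int = 10
    n_mdd_per_site: int = 10
    n_rois: int = 137
    effect_fraction: float = 0.02
    effect_size: float = 0.5
    site_offset_sd: float = 0.5
    beta_age: float = 0.01
    beta_sex: float = 0.2
    noise_sd: float = 1.0
    melancholic_fraction: float = 0.5
    melancholic_effect_size: float | None = None
    site_offset_scale: float = 1.0  # multiplicative site effect; 1 = purely additive
    mode: str = "features"
    n_frames: int = 200
    tr_seconds: float = 2.0
    ar_coef: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_hc_per_site", "n_mdd_per_site"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_rois < 2:
            raise ConfigurationError("n_rois must be >= 2")
        if not 0 <= self.effect_fraction <= 1:
            raise ConfigurationError("effect_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not 0 <= self.melancholic_fraction <= 1:
            raise ConfigurationError("melancholic_fraction must be in [0, 1]")
        if self.mode not in ("features", "timeseries"):
            raise ConfigurationError("mode must be 'features' or 'timeseries'")
        if self.mode == "timeseries" and self.n_frames < 50:
            raise ConfigurationError("n_frames must be >= 50 in timeseries mode")

    @property
    def n_edges(self) -> int:
        return self.n_rois * (self.n_rois - 1) // 2


@dataclass
class GroundTruth:
    """Exactly-as-sampled generative parameters of one synthetic cohort."""

    site_offsets: np.ndarray  # (n_sites, n_edges)
    effect_mask: np.ndarray  # (n_edges,) bool
    true_betas: dict  # {"age": (n_edges,), "sex": (n_edges,)}
    affected_edges: np.ndarray  # indices where effect_mask
    baseline_mean: np.ndarray  # mu_e, (n_edges,)
    site_names: list

    def to_json(self, path) -> None:
        obj = {
            "site_offsets": self.site_offsets.tolist(),
            "effect_mask": self.effect_mask.astype(int).tolist(),
            "true_betas": {k: v.tolist() for k, v in self.true_betas.items()},
            "affected_edges": self.affected_edges.tolist(),
            "baseline_mean": self.baseline_mean.tolist(),
            "site_names": list(self.site_names),
        }
        Path(path).write_text(json.dumps(obj))


@dataclass
class SyntheticCohort:
    """Phenotype table + features (matrix or per-subject time series) + ground truth."""

    phenotypes: pd.DataFrame
    features: np.ndarray | list  # (n, n_edges) array, or list of RoiTimeSeries
    truth: GroundTruth
    edge_index: EdgeIndex
    config: SyntheticConfig

    def __post_init__(self) -> None:
        n = len(self.phenotypes)
        n_feat = len(self.features) if isinstance(self.features, list) else self.features.shape[0]
        if n != n_feat:
            raise ConfigurationError("phenotype rows and feature rows disagree")

    @property
    def labels(self) -> np.ndarray:
        """0 = healthy control, 1 = patient."""
        return (self.phenotypes["diagnosis"].to_numpy() == "MDD").astype(int)

    def subset(self, idx) -> "SyntheticCohort":
        idx = np.asarray(idx)
        pheno = self.phenotypes.iloc[idx].reset_index(drop=True)
        if isinstance(self.features, list):
            feats = [self.features[i] for i in idx]
        else:
            feats = self.features[idx]
        return SyntheticCohort(pheno, feats, self.truth, self.edge_index, self.config)

    def save(self, out_dir) -> None:
        """Write phenotypes.csv, features.h5 (features mode) or timeseries.h5, truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.phenotypes.to_csv(out / "phenotypes.csv", index=False)
        self.truth.to_json(out / "truth.json")
        import h5py

        if isinstance(self.features, np.ndarray):
            with h5py.File(out / "features.h5", "w") as f:
                d = f.create_dataset("features", data=self.features)
                d.attrs["edge_names"] = np.array(self.edge_index.names(), dtype="S")
                f.create_dataset(
                    "subject_id",
                    data=np.array(self.phenotypes["id"], dtype="S"),
                )
        else:
            with h5py.File(out / "timeseries.h5", "w") as f:
                for ts, sid in zip(self.features, self.phenotypes["id"]):
                    g = f.create_group(str(sid))
                    g.create_dataset("data", data=ts.data)
                    g.attrs["tr_seconds"] = ts.tr_seconds
                    for name in ("motion", "wm", "csf", "global_signal", "fd"):
                        tr = getattr(ts, name)
                        if tr is not None:
                            g.create_dataset(name, data=tr)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_phenotypes(config: SyntheticConfig, rng=None) -> pd.DataFrame:
    """Per-site phenotype table: id, site, age, sex, diagnosis, melancholic.

    Ages are uniform on [20, 75]; sex is Bernoulli(0.5) coded 0/1; every site
    receives exactly ``n_hc_per_site`` controls and ``n_mdd_per_site``
    patients, of whom ``round(melancholic_fraction * n_mdd)`` are flagged
    melancholic.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    rows = []
    counter = 0
    n_mel = round(config.melancholic_fraction * config.n_mdd_per_site)
    for s in range(config.n_sites):
        site = f"site{s + 1:02d}"
        for dx, count in (("HC", config.n_hc_per_site), ("MDD", config.n_mdd_per_site)):
            for i in range(count):
                counter += 1
                rows.append(
                    {
                        "id": f"S{counter:04d}",
                        "site": site,
                        "age": rng.uniform(*AGE_RANGE),
                        "sex": int(rng.integers(0, 2)),
                        "diagnosis": dx,
                        "melancholic": bool(dx == "MDD" and i < n_mel),
                    }
                )
    return pd.DataFrame(rows)


def _sample_truth(config: SyntheticConfig, rng: np.random.Generator) -> GroundTruth:
    E = config.n_edges
    n_affected = round(config.effect_fraction * E)
    if config.effect_size > 0 and n_affected < 1:
        warnings.warn(
            "effect_fraction x n_edges < 1: no edge carries a diagnosis effect",
            RuntimeWarning,
            stacklevel=3,
        )
    mask = np.zeros(E, dtype=bool)
    affected = rng.choice(E, size=n_affected, replace=False) if n_affected else np.array([], dtype=int)
    mask[affected] = True
    return GroundTruth(
        site_offsets=rng.normal(0.0, config.site_offset_sd, size=(config.n_sites, E)),
        effect_mask=mask,
        true_betas={
            "age": rng.normal(0.0, config.beta_age, size=E),
            "sex": rng.normal(0.0, config.beta_sex, size=E),
        },
        affected_edges=np.sort(affected),
        baseline_mean=rng.normal(0.25, 0.2, size=E),
        site_names=[f"site{s + 1:02d}" for s in range(config.n_sites)],
    )


def _noise_free_features(
    config: SyntheticConfig, pheno: pd.DataFrame, truth: GroundTruth
) -> np.ndarray:
    """Expected feature value per subject per edge (everything but eps)."""
    age_c = pheno["age"].to_numpy() - np.mean(AGE_RANGE)
    sex = pheno["sex"].to_numpy().astype(float)
    site_idx = np.array([truth.site_names.index(s) for s in pheno["site"]])
    is_mdd = (pheno["diagnosis"].to_numpy() == "MDD").astype(float)
    mel = pheno["melancholic"].to_numpy().astype(bool)

    d = np.full(len(pheno), config.effect_size)
    if config.melancholic_effect_size is not None:
        d[mel] = config.melancholic_effect_size
    d *= is_mdd

    Z = (
        truth.baseline_mean[None, :]
        + age_c[:, None] * truth.true_betas["age"][None, :]
        + sex[:, None] * truth.true_betas["sex"][None, :]
        + config.site_offset_scale * truth.site_offsets[site_idx]
        + (config.noise_sd * d)[:, None] * truth.effect_mask[None, :]
    )
    return Z


def generate_fc_cohort(config: SyntheticConfig, rng=None) -> SyntheticCohort:
    """Sample a feature-mode cohort: subject x edge Fisher-z matrix plus truth.

    The diagnosis effect size ``effect_size`` is the standardized mean
    difference d, i.e. the raw shift on affected edges is d * noise_sd.
    """
    if config.mode != "features":
        raise ConfigurationError("generate_fc_cohort requires mode='features'")
    rng = _as_rng(config.seed if rng is None else rng)
    pheno = generate_phenotypes(config, rng)
    truth = _sample_truth(config, rng)
    Z = _noise_free_features(config, pheno, truth)
    Z = Z + rng.normal(0.0, config.noise_sd, size=Z.shape)
    return SyntheticCohort(pheno, Z, truth, edge_index(config.n_rois), config)


def _nearest_corr(R: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the nearest positive-definite correlation matrix.

    Eigenvalues are floored at ``tol``, then the diagonal is renormalized.
    """
    w, V = np.linalg.eigh((R + R.T) / 2)
    if w.min() >= tol:
        return R
    w = np.clip(w, tol, None)
    A = (V * w) @ V.T
    d = np.sqrt(np.diag(A))
    out = A / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def generate_timeseries_cohort(config: SyntheticConfig, rng=None) -> SyntheticCohort:
    """Sample a time-series-mode cohort of per-subject ROI series.

    Each subject's designed edge correlations are tanh of the subject's
    noise-free feature values (scaled into (-1, 1)); the series is a latent
    multivariate normal with that correlation matrix, passed through an AR(1)
    recursion (which preserves instantaneous correlations).  Synthetic motion
    parameters are low-frequency random walks; white-matter, CSF and global
    traces are smooth random signals; framewise displacement is derived from
    the motion traces.
    """
    if config.mode != "timeseries":
        raise ConfigurationError("generate_timeseries_cohort requires mode='timeseries'")
    if config.n_frames < 50:
        raise ConfigurationError("n_frames must be >= 50 in timeseries mode")
    rng = _as_rng(config.seed if rng is None else rng)
    pheno = generate_phenotypes(config, rng)
    truth = _sample_truth(config, rng)
    Z = _noise_free_features(config, pheno, truth)
    p, T = config.n_rois, config.n_frames
    iu, ju = np.triu_indices(p, k=1)
    subjects = []
    for s in range(len(pheno)):
        R = np.eye(p)
        r = np.tanh(Z[s])
        R[iu, ju] = r
        R[ju, iu] = r
        R = _nearest_corr(R)
        L = np.linalg.cholesky(R + 1e-10 * np.eye(p))
        innov = rng.standard_normal((T, p)) @ L.T
        data = np.empty_like(innov)
        data[0] = innov[0]
        a = config.ar_coef
        for t in range(1, T):
            data[t] = a * data[t - 1] + np.sqrt(1 - a**2) * innov[t]
        # nuisance traces: slow random walks (motion) and smooth physio signals
        motion = np.cumsum(rng.normal(0, 0.02, size=(T, 6)), axis=0)
        smooth = np.cumsum(rng.standard_normal((T, 3)), axis=0)
        smooth = (smooth - smooth.mean(0)) / smooth.std(0)
        wm, csf, gs = smooth.T
        # couple nuisance weakly into the ROI signals so regression has work to do
        coupling = rng.normal(0, 0.1, size=(3, p))
        data = data + smooth @ coupling
        fd = np.abs(np.diff(motion.sum(axis=1), prepend=motion[0].sum())) + rng.uniform(
            0, 0.05, size=T
        )
        subjects.append(
            RoiTimeSeries(
                data=data,
                tr_seconds=config.tr_seconds,
                motion=motion,
                wm=wm,
                csf=csf,
                global_signal=gs,
                fd=fd,
                subject_id=str(pheno["id"].iloc[s]),
            )
        )
    return SyntheticCohort(pheno, subjects, truth, edge_index(config.n_rois), config)
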