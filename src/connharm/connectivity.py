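"""ROI time series to Fisher-z functional-connectivity features.

The entry point is a per-subject matrix of region-of-interest (ROI) signal
time courses together with optional nuisance traces (six rigid-body motion
parameters, white-matter and cerebrospinal-fluid mean signals, the global
brain signal, and a framewise-displacement trace in millimetres).  The
pipeline applied by :func:`preprocess_and_fc` is fixed:

    censor (scrub) -> band-pass filter -> nuisance regression
           -> pairwise Pearson correlation -> Fisher z

Frames flagged by the framewise-displacement threshold are linearly
interpolated before filtering (so the IIR filter sees a gapless series) and
excluded again before the correlation step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from connharm.errors import DataError, ParameterError, QualityError

logger = logging.getLogger(__name__)

#: correlations are clipped to this magnitude before arctanh so z stays finite
R_CLIP = 1.0 - 1e-7


@dataclass
class RoiTimeSeries:
    """One subject's T x p ROI signal matrix plus optional nuisance traces.

    Parameters
    ----------
    data : ndarray of shape (T, p)
        ROI signal time courses, arbitrary units.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    motion : ndarray of shape (T, 6), optional
        Rigid-body realignment parameters.
    wm, csf, global_signal : ndarray of shape (T,), optional
        Mean white-matter, cerebrospinal-fluid and whole-brain traces.
    fd : ndarray of shape (T,), optional
        Framewise displacement in millimetres, used for scrubbing.
    subject_id : str
        Identifier used in quality-error messages.
    """

    data: np.ndarray
    tr_seconds: float
    motion: np.ndarray | None = None
    wm: np.ndarray | None = None
    csf: np.ndarray | None = None
    global_signal: np.ndarray | None = None
    fd: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise DataError("time-series data must be a T x p matrix with T >= 2")
        if self.tr_seconds <= 0:
            raise DataError("tr_seconds must be positive")
        T = self.data.shape[0]
        for name in ("motion", "wm", "csf", "global_signal", "fd"):
            tr = getattr(self, name)
            if tr is None:
                continue
            tr = np.asarray(tr, dtype=float)
            setattr(self, name, tr)
            if tr.shape[0] != T:
                raise DataError(f"nuisance trace '{name}' length {tr.shape[0]} != T={T}")
        if self.motion is not None and (self.motion.ndim != 2 or self.motion.shape[1] != 6):
            raise DataError("motion must be a T x 6 matrix")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class EdgeIndex:
    """Canonical ordering of the p(p-1)/2 region pairs: 0-based upper triangle, row-major."""

    p: int
    pairs: tuple = field(repr=False, default=())

    @property
    def n_edges(self) -> int:
        return len(self.pairs)

    def names(self, roi_names=None) -> list[str]:
        """Edge labels ``roi_i__roi_j`` for feature-matrix headers."""
        if roi_names is None:
            roi_names = [f"roi{i}" for i in range(self.p)]
        return [f"{roi_names[i]}__{roi_names[j]}" for i, j in self.pairs]


def edge_index(p: int) -> EdgeIndex:
    """Canonical edge index for ``p`` regions: all (i, j) with i < j, row-major.

    For the 137-region cortical parcellation this yields 9,316 edges.
    """
    if p < 2:
        raise ParameterError(f"need at least 2 regions, got {p}")
    iu, ju = np.triu_indices(p, k=1)
    return EdgeIndex(p=p, pairs=tuple(zip(iu.tolist(), ju.tolist())))


@dataclass
class ConnectivityVector:
    """Fisher-z connectivity features for one subject, in edge-index order."""

    z: np.ndarray
    edge_index: EdgeIndex
    n_frames_used: int

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (self.edge_index.n_edges,):
            raise DataError("z length does not match edge index")
        if not np.all(np.isfinite(self.z)):
            raise DataError("non-finite Fisher-z entries")


def fisher_z(r):
    """Fisher z-transformation arctanh(r), with |r| clipped to 1 - 1e-7.

    Variance-stabilizes Pearson correlations for downstream linear modelling.
    Accepts scalars or arrays; raises for |r| > 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0):
        raise ParameterError("correlation magnitude exceeds 1")
    out = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    return float(out) if out.ndim == 0 else out


def bandpass_filter(
    ts: RoiTimeSeries,
    low_hz: float = 0.008,
    high_hz: float = 0.1,
    order: int = 5,
) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass of every ROI column and nuisance trace.

    The default 0.008-0.1 Hz band is the standard resting-state BOLD band.
    Nuisance traces are filtered with the same filter so the later regression
    cannot reintroduce out-of-band variance.  Forward-backward (filtfilt)
    application gives zero phase distortion; output length equals input length.
    """
    nyquist = 0.5 / ts.tr_seconds
    if not (0 <= low_hz < high_hz):
        raise ParameterError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ParameterError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist:.4f} Hz"
        )
    if low_hz > 0:
        sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos")
    else:
        sos = signal.butter(order, high_hz, btype="lowpass", fs=1.0 / ts.tr_seconds, output="sos")

    def _filt(x):
        return signal.sosfiltfilt(sos, x, axis=0)

    updates = {"data": _filt(ts.data)}
    for name in ("motion", "wm", "csf", "global_signal"):
        tr = getattr(ts, name)
        if tr is not None:
            updates[name] = _filt(tr)
    return replace(ts, **updates)


def censor_frames(
    ts: RoiTimeSeries,
    fd_threshold_mm: float = 0.5,
    min_frames: int = 50,
) -> tuple[RoiTimeSeries, np.ndarray]:
    """Scrub frames whose framewise displacement exceeds the threshold.

    Returns the censored series and the boolean kept-mask (True = retained).
    Raises :class:`QualityError` naming the subject if fewer than
    ``min_frames`` frames survive.
    """
    if ts.fd is None:
        raise DataError("framewise-displacement trace required for scrubbing")
    if fd_threshold_mm <= 0:
        raise ParameterError("fd_threshold_mm must be positive")
    keep = ts.fd <= fd_threshold_mm
    n_kept = int(keep.sum())
    if n_kept < min_frames:
        raise QualityError(
            f"subject '{ts.subject_id}': only {n_kept} frames below "
            f"FD {fd_threshold_mm} mm (minimum {min_frames})"
        )
    updates = {"data": ts.data[keep]}
    for name in ("motion", "wm", "csf", "global_signal", "fd"):
        tr = getattr(ts, name)
        if tr is not None:
            updates[name] = tr[keep]
    return replace(ts, **updates), keep


def _interpolate_censored(ts: RoiTimeSeries, keep: np.ndarray) -> RoiTimeSeries:
    """Linearly interpolate censored frames so an IIR filter sees a gapless series."""
    if keep.all():
        return ts
    t = np.arange(ts.n_frames, dtype=float)
    tk = t[keep]

    def _interp(x):
        if x.ndim == 1:
            return np.interp(t, tk, x[keep])
        return np.column_stack([np.interp(t, tk, x[keep, j]) for j in range(x.shape[1])])

    updates = {"data": _interp(ts.data)}
    for name in ("motion", "wm", "csf", "global_signal"):
        tr = getattr(ts, name)
        if tr is not None:
            updates[name] = _interp(tr)
    return replace(ts, **updates)


def regress_nuisance(ts: RoiTimeSeries, use_gsr: bool = True) -> RoiTimeSeries:
    """Regress nuisance parameters out of every ROI column by ordinary least squares.

    The design holds an intercept, the six motion parameters, the white-matter
    and cerebrospinal-fluid traces, and — when ``use_gsr`` — the global brain
    signal (nine regressors in total).  Each column is replaced by its
    residual, which is orthogonal to every regressor.  Collinear design
    columns are dropped with a logged warning.
    """
    for name in ("motion", "wm", "csf"):
        if getattr(ts, name) is None:
            raise DataError(f"nuisance regression requires '{name}'")
    if use_gsr and ts.global_signal is None:
        raise DataError("use_gsr=True requires the global-signal trace")
    cols = [np.ones(ts.n_frames), *ts.motion.T, ts.wm, ts.csf]
    if use_gsr:
        cols.append(ts.global_signal)
    D = np.column_stack(cols)
    # drop collinear columns via pivoted QR
    from scipy.linalg import qr as pivoted_qr

    _, r, piv = pivoted_qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(D.shape) * np.finfo(float).eps
    if np.any(diag < tol):
        rank = int(np.sum(diag > tol))
        kept = np.sort(piv[:rank])
        logger.warning(
            "nuisance design rank-deficient: dropping %d collinear column(s)",
            D.shape[1] - rank,
        )
        D = D[:, kept]
    beta, *_ = np.linalg.lstsq(D, ts.data, rcond=None)
    resid = ts.data - D @ beta
    return replace(ts, data=resid)


def compute_fc(ts: RoiTimeSeries, index: EdgeIndex | None = None) -> ConnectivityVector:
    """Pairwise Pearson correlations between ROI columns, Fisher z-transformed.

    Zero-variance columns yield z = 0 on all their edges, with a warning.
    """
    if ts.n_frames < 3:
        raise DataError("need at least 3 frames to correlate")
    if index is None:
        index = edge_index(ts.n_rois)
    elif index.p != ts.n_rois:
        raise DataError("edge index does not match region count")
    X = ts.data - ts.data.mean(axis=0)
    sd = X.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance ROI column(s); their edges set to z=0",
            RuntimeWarning,
            stacklevel=2,
        )
        sd = np.where(dead, 1.0, sd)
    Xn = X / sd
    R = (Xn.T @ Xn) / ts.n_frames
    iu, ju = np.triu_indices(ts.n_rois, k=1)
    r = np.clip(R[iu, ju], -1.0, 1.0)
    bad_edge = dead[iu] | dead[ju]
    z = fisher_z(r)
    z[bad_edge] = 0.0
    return ConnectivityVector(z=z, edge_index=index, n_frames_used=ts.n_frames)


def preprocess_and_fc(
    ts: RoiTimeSeries,
    low_hz: float = 0.008,
    high_hz: float = 0.1,
    fd_threshold_mm: float = 0.5,
    use_gsr: bool = True,
    min_frames: int = 50,
    discard_initial: int = 0,
    filter_order: int = 5,
) -> ConnectivityVector:
    """Full single-subject pipeline: scrub, filter, regress nuisance, correlate.

    ``discard_initial`` drops leading frames before anything else (for series
    that still contain pre-steady-state volumes); the default assumes the
    input is already trimmed.
    """
    logger.info(
        "pipeline order: censor -> band-pass -> nuisance regression -> correlation -> Fisher z"
    )
    if discard_initial:
        updates = {"data": ts.data[discard_initial:]}
        for name in ("motion", "wm", "csf", "global_signal", "fd"):
            tr = getattr(ts, name)
            if tr is not None:
                updates[name] = tr[discard_initial:]
        ts = replace(ts, **updates)
    if ts.fd is not None:
        keep = ts.fd <= fd_threshold_mm
        if int(keep.sum()) < min_frames:
            raise QualityError(
                f"subject '{ts.subject_id}': only {int(keep.sum())} frames below "
                f"FD {fd_threshold_mm} mm (minimum {min_frames})"
            )
        ts = _interpolate_censored(ts, keep)
    else:
        keep = np.ones(ts.n_frames, dtype=bool)
    ts = bandpass_filter(ts, low_hz, high_hz, order=filter_order)
    ts = regress_nuisance(ts, use_gsr=use_gsr)
    updates = {"data": ts.data[keep]}
    for name in ("motion", "wm", "csf", "global_signal", "fd"):
        tr = getattr(ts, name)
        if tr is not None:
            updates[name] = tr[keep]
    return compute_fc(replace(ts, **updates))
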