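"""Temporal cleanup of ROI BOLD time series.

The pipeline order is fixed: discard initial volumes, remove linear trends,
band-pass filter (zero-phase Butterworth), then regress out nuisance
signals. Nuisance regressors are detrended and filtered identically to the
data before regression, so signal and regressors live in the same band.
All operations act column-wise and never mix nodes.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class RoiTimeSeries:
    """One subject's T x N regional BOLD signal matrix.

    Parameters
    ----------
    subject_id : str
        Subject label.
    data : ndarray, shape (T, N)
        One column per region of interest, arbitrary BOLD units.
    sampling_interval_s : float
        Repetition time (TR) in seconds.
    node_ids : tuple of str
        Region labels aligned with the columns of ``data``.
    nuisance : ndarray, shape (T, K), optional
        Nuisance regressors (e.g. Friston-24 motion parameters plus white
        matter and cerebrospinal-fluid signals).
    motion_max_disp_mm, motion_max_rot_deg : float, optional
        Maximum head displacement (mm) / rotation (degrees) in any
        direction, used for motion screening.
    """

    subject_id: str
    data: np.ndarray
    sampling_interval_s: float
    node_ids: tuple = ()
    nuisance: np.ndarray | None = None
    motion_max_disp_mm: float | None = None
    motion_max_rot_deg: float | None = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("data must be a T x N matrix")
        if not np.isfinite(data).all():
            raise ValueError("time series contains missing/non-finite values")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval_s must be positive")
        if self.node_ids and len(self.node_ids) != data.shape[1]:
            raise ValueError("node_ids length must match number of columns")
        if self.nuisance is not None:
            nuis = np.asarray(self.nuisance, dtype=float)
            object.__setattr__(self, "nuisance", nuis)
            if nuis.shape[0] != data.shape[0]:
                raise ValueError("nuisance must have the same number of rows as data")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    def replace(self, **kw) -> "RoiTimeSeries":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class PreprocessConfig:
    """Temporal preprocessing parameters (defaults match a TR=2 s protocol)."""

    drop_initial: int = 10
    low_hz: float = 0.01
    high_hz: float = 0.1
    filter_order: int = 4
    max_disp_mm: float = 2.0
    max_rot_deg: float = 2.0
    on_missing_motion: str = "warn"  # "warn" or "fail"


def screen_motion(
    ts: RoiTimeSeries,
    disp_mm: float = 2.0,
    rot_deg: float = 2.0,
    on_missing: str = "warn",
) -> bool:
    """Return True if the subject passes the head-motion criterion.

    A subject fails when maximum displacement exceeds ``disp_mm`` or maximum
    rotation exceeds ``rot_deg`` (strict inequality: exactly at the limit
    still passes). Subjects without a motion summary are "unscreened": with
    ``on_missing="warn"`` they pass with a warning, with ``"fail"`` an error
    is raised.
    """
    if ts.motion_max_disp_mm is None or ts.motion_max_rot_deg is None:
        msg = f"subject {ts.subject_id}: no motion summary, unscreened"
        if on_missing == "fail":
            raise ValueError(msg)
        warnings.warn(msg)
        return True
    return not (ts.motion_max_disp_mm > disp_mm or ts.motion_max_rot_deg > rot_deg)


def drop_initial_volumes(ts: RoiTimeSeries, n: int = 10) -> RoiTimeSeries:
    """Discard the first ``n`` volumes (signal-equilibration period)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= ts.n_timepoints:
        raise ValueError(f"cannot drop {n} of {ts.n_timepoints} volumes")
    nuis = None if ts.nuisance is None else ts.nuisance[n:]
    return ts.replace(data=ts.data[n:], nuisance=nuis)


def detrend_linear(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Remove per-column least-squares linear trends (and hence the mean).

    Nuisance regressors, when present, are detrended identically.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints to detrend")
    data = signal.detrend(ts.data, axis=0, type="linear")
    nuis = ts.nuisance
    if nuis is not None:
        nuis = signal.detrend(nuis, axis=0, type="linear")
    return ts.replace(data=data, nuisance=nuis)


def bandpass(
    ts: RoiTimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    order: int = 4,
) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass filter applied forward and backward.

    The forward-backward pass doubles the effective order and cancels phase
    shifts, preserving the relative timing (and therefore correlation
    structure) of in-band components. Edges are handled by reflection
    padding. Nuisance regressors are filtered identically.
    """
    nyquist = 0.5 / ts.sampling_interval_s
    if high_hz >= nyquist:
        raise ValueError(
            f"high cutoff {high_hz} Hz is at/above the Nyquist frequency "
            f"{nyquist} Hz for TR={ts.sampling_interval_s} s"
        )
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.sampling_interval_s, output="sos")

    def _filt(x):
        return signal.sosfiltfilt(sos, x, axis=0, padtype="odd")

    nuis = None if ts.nuisance is None else _filt(ts.nuisance)
    return ts.replace(data=_filt(ts.data), nuisance=nuis)


def regress_nuisance(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Residualize every column on [intercept | nuisance regressors].

    Requires T >= 2K (K regressors) and a full-rank design; a rank-deficient
    design raises an error naming the collinear columns.
    """
    if ts.nuisance is None:
        raise ValueError("no nuisance regressors attached")
    T, K = ts.nuisance.shape
    if T < 2 * K:
        raise ValueError(f"T={T} < 2*K={2 * K}: too few timepoints for {K} regressors")
    X = np.column_stack([np.ones(T), ts.nuisance])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = sorted(piv[rank:])
        names = [("intercept" if j == 0 else f"nuisance[{j - 1}]") for j in bad]
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {names}")
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    resid = ts.data - X @ beta
    return ts.replace(data=resid)


def preprocess(ts: RoiTimeSeries, config: PreprocessConfig | None = None) -> RoiTimeSeries:
    """Full temporal pipeline: drop -> detrend -> band-pass -> nuisance."""
    cfg = config or PreprocessConfig()
    out = drop_initial_volumes(ts, cfg.drop_initial) if cfg.drop_initial else ts
    out = detrend_linear(out)
    out = bandpass(out, cfg.low_hz, cfg.high_hz, cfg.filter_order)
    if out.nuisance is not None:
        out = regress_nuisance(out)
    return out
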