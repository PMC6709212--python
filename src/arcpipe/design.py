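"""First-level fMRI design construction.

Builds the task regressors of the variable-epoch analysis: per-trial boxcars
whose duration equals the observed response time (controlling the
time-on-task effect), optionally parametrically modulated in amplitude by
the per-trial conflict estimate d (or by risk / standardized reward in the
control analyses).  Also provides the canonical double-gamma HRF, the
discrete-cosine high-pass drift basis, processed motion nuisance regressors,
framewise displacement and motion scrubbing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "EpochSpec",
    "build_epochs",
    "hrf",
    "convolve_regressor",
    "dct_drift_basis",
    "motion_nuisance",
    "framewise_displacement",
    "scrub_mask",
    "build_design_matrix",
]

RESPONSE_WINDOW = 3.5        # s; response cutoff of the task
HRF_LENGTH = 32.0            # s
DEFAULT_OVERSAMPLING = 16
DEFAULT_CUTOFF_HZ = 0.01
FD_THRESHOLD_MM = 0.9
N_DISCARD_INITIAL = 4
HEAD_RADIUS_MM = 50.0


@dataclass
class EpochSpec:
    """Per-trial boxcar description: onsets and durations in seconds,
    dimensionless amplitudes (0 for missing responses on modulators)."""

    onsets: np.ndarray
    durations: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if not (len(self.onsets) == len(self.durations) == len(self.amplitudes)):
            raise ValueError("onsets, durations, amplitudes must align")
        if len(self.onsets) and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be positive")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")


def build_epochs(
    events: pd.DataFrame,
    mode: str = "variable",
    modulator: str = "none",
    fixed_window: float = RESPONSE_WINDOW,
    center: bool = True,
) -> EpochSpec:
    """Boxcar epochs for one participant's run.

    ``events`` needs columns ``onset`` and ``rt`` (NaN where the response is
    missing) plus, depending on ``modulator``: ``d_hat`` (conflict), ``risk``
    or ``reward_z``.  In ``variable`` mode each trial's duration is its
    response time (missing responses fall back to ``fixed_window``); in
    ``fixed`` mode every duration is ``fixed_window``.  Modulator amplitudes
    are zeroed on missing-response trials and (by default) mean-centered
    across non-missing trials so the unmodulated control regressor absorbs
    the mean deliberation response.
    """
    if mode not in ("variable", "fixed"):
        raise ValueError(f"unknown epoch mode: {mode}")
    onsets = events["onset"].to_numpy(dtype=float)
    rt = events["rt"].to_numpy(dtype=float)
    missing = ~np.isfinite(rt)

    if mode == "variable":
        durations = np.where(missing, fixed_window, rt)
    else:
        durations = np.full(len(events), float(fixed_window))

    if modulator == "none":
        amplitudes = np.ones(len(events))
    else:
        col = {"conflict": "d_hat", "risk": "risk", "reward": "reward_z"}.get(modulator)
        if col is None:
            raise ValueError(f"unknown modulator: {modulator}")
        amplitudes = events[col].to_numpy(dtype=float).copy()
        if center and (~missing).any():
            amplitudes = amplitudes - amplitudes[~missing].mean()
        amplitudes[missing] = 0.0
    return EpochSpec(onsets=onsets, durations=durations, amplitudes=amplitudes)


def hrf(dt: float) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled every ``dt`` s.

    Peak delay 6 s, undershoot delay 16 s, unit dispersions, 6:1
    peak-to-undershoot ratio, 32 s support; normalized to unit peak (the
    percent-signal-change convention used downstream).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, HRF_LENGTH + dt / 2, dt)
    h = _gamma_dist.pdf(t, a=6.0, scale=1.0) - _gamma_dist.pdf(t, a=16.0, scale=1.0) / 6.0
    return h / h.max()


def sample_boxcar(epochs: EpochSpec, dt: float, n_samples: int) -> np.ndarray:
    """Sample the stimulus function on a grid of bin width ``dt``.

    Partial bins are weighted by their overlap with the epoch, so the
    discrete integral ``box.sum() * dt`` equals the continuous one
    (sum of amplitude * duration) exactly for in-range epochs.
    """
    box = np.zeros(n_samples)
    for onset, dur, amp in zip(epochs.onsets, epochs.durations, epochs.amplitudes):
        s = onset / dt
        e = (onset + dur) / dt
        i0 = int(np.floor(s))
        i1 = int(np.floor(e))
        if i0 >= n_samples:
            continue
        if i0 == i1:
            box[i0] += amp * (e - s)
            continue
        box[i0] += amp * (i0 + 1 - s)
        box[i0 + 1: min(i1, n_samples)] += amp
        if i1 < n_samples:
            box[i1] += amp * (e - i1)
    return box


def convolve_regressor(
    epochs: EpochSpec,
    frame_times: np.ndarray,
    oversampling: int = DEFAULT_OVERSAMPLING,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at the scan times.

    The boxcar is built on a grid ``oversampling`` times finer than the scan
    spacing (onsets need not align with scans), convolved with the canonical
    HRF, and read out at ``frame_times``.  Epochs extending past the last
    frame are truncated with a warning.
    """
    if oversampling < 1:
        raise ValueError("oversampling must be >= 1")
    frame_times = np.asarray(frame_times, dtype=float)
    if len(epochs.onsets) == 0:
        return np.zeros(len(frame_times))
    tr = frame_times[1] - frame_times[0] if len(frame_times) > 1 else 1.0
    dt = tr / oversampling
    t_end = frame_times[-1] + tr
    n_hi = int(np.ceil(t_end / dt)) + 1
    if np.any(epochs.onsets + epochs.durations > t_end):
        warnings.warn("epoch extends past the last frame; truncated")
    box = sample_boxcar(epochs, dt, n_hi)
    kernel = hrf(dt)
    col = np.convolve(box, kernel)[:n_hi] * dt
    idx = np.round(frame_times / dt).astype(int)
    return col[np.clip(idx, 0, n_hi - 1)]


def dct_drift_basis(n_scans: int, tr: float, cutoff_hz: float = DEFAULT_CUTOFF_HZ):
    """Orthonormal DCT-II high-pass basis with frequencies below ``cutoff_hz``.

    The number of columns is floor(2 * n_scans * tr * cutoff_hz).
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff frequency must be positive")
    n_cols = int(np.floor(2.0 * n_scans * tr * cutoff_hz))
    if n_cols == 0:
        warnings.warn("run too short for any drift column at this cutoff")
        return np.zeros((n_scans, 0))
    t = np.arange(n_scans)
    basis = np.column_stack(
        [
            np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * t + 1) / (2 * n_scans))
            for k in range(1, n_cols + 1)
        ]
    )
    return basis


def motion_nuisance(motion: np.ndarray) -> np.ndarray:
    """Demean, linearly detrend, and Gram-Schmidt orthogonalize the six
    motion traces (in column order).  Degenerate columns come back as zeros
    with a warning."""
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion must have 6 columns")
    if m.shape[0] < 3:
        raise ValueError("need at least 3 scans")
    n = m.shape[0]
    t = np.arange(n) - (n - 1) / 2.0
    out = np.empty_like(m)
    for j in range(6):
        col = m[:, j] - m[:, j].mean()
        col = col - (col @ t) / (t @ t) * t       # remove linear trend
        for i in range(j):
            prev = out[:, i]
            nrm = prev @ prev
            if nrm > 1e-12:
                col = col - (col @ prev) / nrm * prev
        if np.sqrt(col @ col) < 1e-10 * max(1.0, np.abs(m[:, j]).max()):
            warnings.warn(f"motion column {j} is degenerate after processing; zeroed")
            col = np.zeros(n)
        out[:, j] = col
    return out


def framewise_displacement(motion: np.ndarray, head_radius_mm: float = HEAD_RADIUS_MM):
    """FD_t = sum |delta translations| + radius * sum |delta rotations|; FD_0 = 0.

    Columns 0-2 are translations (mm), 3-5 rotations (radians).
    """
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion must have 6 columns")
    d = np.abs(np.diff(m, axis=0))
    fd = np.zeros(m.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return fd


def scrub_mask(
    fd: np.ndarray,
    threshold_mm: float = FD_THRESHOLD_MM,
    n_discard_initial: int = N_DISCARD_INITIAL,
) -> np.ndarray:
    """Boolean keep-mask: False for the first ``n_discard_initial`` scans and
    wherever framewise displacement exceeds ``threshold_mm``."""
    if threshold_mm <= 0:
        raise ValueError("threshold must be positive")
    fd = np.asarray(fd, dtype=float)
    keep = fd <= threshold_mm
    keep[:n_discard_initial] = False
    return keep


@dataclass
class DesignInfo:
    matrix: pd.DataFrame
    task_columns: list = field(default_factory=list)


def build_design_matrix(
    events: pd.DataFrame,
    n_scans: int,
    tr: float,
    mode: str = "variable",
    modulators=("conflict",),
    motion: np.ndarray | None = None,
    fd_threshold_mm: float = FD_THRESHOLD_MM,
    n_discard_initial: int = N_DISCARD_INITIAL,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    oversampling: int = DEFAULT_OVERSAMPLING,
    fixed_window: float = RESPONSE_WINDOW,
    center_modulators: bool = True,
) -> DesignInfo:
    """Assemble the full first-level design matrix.

    Columns: one unmodulated task control regressor, one parametric
    modulation regressor per requested modulator, the DCT drift basis,
    processed motion nuisance regressors, per-scan spike regressors for
    scrubbed volumes (high-motion frames and the initial discarded
    acquisitions), and a constant.  Scrubbing by spike regressors keeps the
    time axis intact for the drift basis.
    """
    frame_times = np.arange(n_scans) * tr
    cols: dict[str, np.ndarray] = {}

    control = build_epochs(events, mode=mode, modulator="none", fixed_window=fixed_window)
    cols["task_control"] = convolve_regressor(control, frame_times, oversampling)
    task_columns = ["task_control"]
    for mod in modulators:
        if mod == "none":
            continue
        ep = build_epochs(
            events, mode=mode, modulator=mod,
            fixed_window=fixed_window, center=center_modulators,
        )
        name = f"task_{mod}"
        cols[name] = convolve_regressor(ep, frame_times, oversampling)
        task_columns.append(name)

    drift = dct_drift_basis(n_scans, tr, cutoff_hz)
    for k in range(drift.shape[1]):
        cols[f"drift_{k + 1}"] = drift[:, k]

    if motion is not None:
        proc = motion_nuisance(motion)
        for k in range(6):
            cols[f"motion_{k + 1}"] = proc[:, k]
        fd = framewise_displacement(motion)
        keep = scrub_mask(fd, fd_threshold_mm, n_discard_initial)
    else:
        keep = scrub_mask(np.zeros(n_scans), fd_threshold_mm, n_discard_initial)
    for t_idx in np.flatnonzero(~keep):
        spike = np.zeros(n_scans)
        spike[t_idx] = 1.0
        cols[f"scrub_{t_idx}"] = spike

    cols["constant"] = np.ones(n_scans)
    X = pd.DataFrame(cols, index=frame_times)
    X.index.name = "frame_time"
    for name in task_columns:
        if np.allclose(X[name].to_numpy(), 0.0):
            raise ValueError(f"task column {name!r} is all zero")
    return DesignInfo(matrix=X, task_columns=task_columns)
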