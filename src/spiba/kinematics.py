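"""Kinematic derivatives, forward/backward segmentation, behavioral metrics.

Pointing trials are out-and-back motions: a goal-directed forward reach
to a target followed by an uninstructed, spontaneous retraction. The two
segments are split at the sample where the hand-to-target distance is
minimal — the hand's linear velocity is near zero there — and bounded by
a sustained speed threshold relative to the trial's maximum speed.

Derivatives of position/orientation amplify instrumentation noise, so
they are estimated with local-polynomial (Savitzky-Golay) smoothing
differentiation rather than naive finite differences; endpoints use
one-sided polynomial fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import savgol_filter

from .micromovements import detect_extrema
from .signal_core import (
    InputError,
    SessionRecord,
    SpibaError,
    TimeSeries,
    TrialRecord,
    ValidationError,
)

__all__ = [
    "Trajectory",
    "MovementSegment",
    "differentiate",
    "compute_speed",
    "compute_angular_acceleration",
    "segment_trial",
    "behavioral_metrics",
    "paired_condition_test",
    "read_trajectory_csv",
]

#: Default smoothing-differentiation window (samples; ~87 ms at 240 Hz).
DEFAULT_SMOOTH_WINDOW = 21
#: Default local polynomial order.
DEFAULT_POLY_ORDER = 3
#: Fraction of trial max speed below which the hand counts as resting.
DEFAULT_REST_SPEED_FRAC = 0.05
#: Minimum time (s) the speed must stay past the threshold to switch state.
SUSTAIN_S = 0.05


@dataclass(frozen=True)
class Trajectory:
    """Position (cm) and optional angular-rate channel on one time base."""

    t: np.ndarray                    # seconds
    pos: np.ndarray                  # (n, 3) cm
    ang_rate: np.ndarray | None = None  # (n,) or (n, 3) deg/s
    fs: float = 240.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=float))
        if self.pos.ndim != 2 or self.pos.shape[1] != 3:
            raise ValidationError("pos must be (n, 3)")
        if len(self.t) != len(self.pos):
            raise ValidationError("t and pos length mismatch")
        if not np.all(np.isfinite(self.pos)):
            raise ValidationError("non-finite position samples")
        if self.ang_rate is not None:
            ar = np.asarray(self.ang_rate, dtype=float)
            if len(ar) != len(self.t):
                raise ValidationError("ang_rate length mismatch")
            object.__setattr__(self, "ang_rate", ar)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class MovementSegment:
    """Half-open sample span [start, end) of one movement class in a trial."""

    trial_index: int
    kind: str                 # "forward" | "backward"
    start: int
    end: int
    fs: float
    peak_count: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("forward", "backward"):
            raise ValidationError(f"unknown segment kind {self.kind!r}")
        if not self.end > self.start:
            raise ValidationError("segment must be non-empty")

    @property
    def movement_time(self) -> float:
        return (self.end - self.start) / self.fs


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------

def differentiate(
    ts: TimeSeries,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    poly_order: int = DEFAULT_POLY_ORDER,
    order: int = 1,
) -> TimeSeries:
    """Smoothing differentiation by local polynomial fits.

    Exact for polynomials up to ``poly_order``; endpoints are handled by
    one-sided fits. The default 21-sample window at 240 Hz (~87 ms)
    suppresses sample-to-sample instrumentation noise that naive finite
    differences would amplify.
    """
    if smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd")
    if smooth_window < poly_order + 2:
        raise ValueError("smooth_window must be >= poly_order + 2")
    if smooth_window > len(ts):
        raise InputError(
            f"window of {smooth_window} longer than series of {len(ts)}"
        )
    dv = savgol_filter(
        ts.v, smooth_window, poly_order, deriv=order,
        delta=1.0 / ts.fs, mode="interp",
    )
    return TimeSeries(t=ts.t, v=dv, fs=ts.fs,
                      channel_id=f"d{order}_{ts.channel_id}", units=ts.units)


def _component_derivative(
    t: np.ndarray, x: np.ndarray, fs: float, window: int, poly: int
) -> np.ndarray:
    return savgol_filter(x, window, poly, deriv=1, delta=1.0 / fs, mode="interp")


def compute_speed(
    traj: Trajectory,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    poly_order: int = DEFAULT_POLY_ORDER,
) -> TimeSeries:
    """Euclidean norm of the smoothed first derivative of position (cm/s)."""
    vel = np.column_stack([
        _component_derivative(traj.t, traj.pos[:, k], traj.fs,
                              smooth_window, poly_order)
        for k in range(3)
    ])
    speed = np.linalg.norm(vel, axis=1)
    return TimeSeries(t=traj.t, v=speed, fs=traj.fs,
                      channel_id="speed", units="cm/s")


def compute_angular_acceleration(
    traj: Trajectory,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    poly_order: int = DEFAULT_POLY_ORDER,
) -> TimeSeries:
    """|d/dt| of the angular-speed magnitude (deg/s^2), non-negative.

    The angular-rate channel may be a scalar rate or a 3-component
    angular velocity; the magnitude is differentiated and the absolute
    value taken so the result is a magnitude waveform suitable for the
    amplitude normalization.
    """
    if traj.ang_rate is None:
        raise SpibaError("trajectory has no angular-rate channel")
    ar = traj.ang_rate
    mag = np.linalg.norm(ar, axis=1) if ar.ndim == 2 else np.abs(ar)
    acc = savgol_filter(mag, smooth_window, poly_order, deriv=1,
                        delta=1.0 / traj.fs, mode="interp")
    return TimeSeries(t=traj.t, v=np.abs(acc), fs=traj.fs,
                      channel_id="ang_accel", units="deg/s^2")


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _sustained_crossing(mask: np.ndarray, run: int) -> int | None:
    """Start index of the first run of ``run`` consecutive True samples."""
    count = 0
    for i in range(len(mask)):
        count = count + 1 if mask[i] else 0
        if count >= run:
            return int(i - run + 1)
    return None


def segment_trial(
    traj: Trajectory,
    trial: TrialRecord,
    target_pos: np.ndarray,
    rest_speed_frac: float = DEFAULT_REST_SPEED_FRAC,
    speed: TimeSeries | None = None,
    window: tuple[int, int] | None = None,
) -> tuple[MovementSegment, MovementSegment]:
    """Split one trial into its forward reach and backward retraction.

    The split is the sample of minimum hand-to-target distance within the
    trial window; the forward segment starts at movement onset (speed
    above ``rest_speed_frac`` x trial max speed sustained >= 50 ms) and
    the backward segment ends at movement offset (speed back below the
    threshold, sustained). When no sustained rest is found the segment
    extends to the trial boundary with a warning.
    """
    target = np.asarray(target_pos, dtype=float)
    if window is None:
        lo = int(np.searchsorted(traj.t, trial.event_times.get("prompt", traj.t[0])))
        hi_t = trial.event_times.get("response", traj.t[-1])
        hi = int(np.searchsorted(traj.t, hi_t, side="right"))
    else:
        lo, hi = window
    if hi - lo < 3:
        raise SpibaError(f"trial {trial.trial_index}: window too short")

    dist = np.linalg.norm(traj.pos[lo:hi] - target, axis=1)
    split_rel = int(np.argmin(dist))
    if split_rel in (0, len(dist) - 1):
        raise SpibaError(
            f"trial {trial.trial_index}: distance minimum at window edge"
        )
    split = lo + split_rel

    if speed is None:
        speed = compute_speed(traj)
    sp = speed.v[lo:hi]
    thresh = rest_speed_frac * float(np.max(sp))
    run = max(int(round(SUSTAIN_S * traj.fs)), 1)

    onset = _sustained_crossing(sp[: split_rel] > thresh, run)
    if onset is None:
        warnings.warn(
            f"trial {trial.trial_index}: no movement onset found, "
            "forward segment extends to trial start", stacklevel=2,
        )
        onset = 0
    # the offset is where speed falls BACK below threshold: skip the
    # near-zero dip at the turnaround by first waiting for the backward
    # motion to rise above threshold
    above = np.nonzero(sp[split_rel:] > thresh)[0]
    off = None
    if len(above):
        resume = split_rel + int(above[0])
        off = _sustained_crossing(sp[resume:] < thresh, run)
        if off is not None:
            offset = resume + off
    if off is None:
        warnings.warn(
            f"trial {trial.trial_index}: no movement offset found, "
            "backward segment extends to trial end", stacklevel=2,
        )
        offset = len(sp)

    forward = MovementSegment(trial.trial_index, "forward",
                              lo + onset, split, traj.fs)
    backward = MovementSegment(trial.trial_index, "backward",
                               split, lo + offset, traj.fs)
    return forward, backward


# ---------------------------------------------------------------------------
# behavioral metrics
# ---------------------------------------------------------------------------

def behavioral_metrics(
    session: SessionRecord,
    segments: dict[int, tuple[MovementSegment, MovementSegment]],
    ang_accel: TimeSeries | None = None,
    scale_max_s: float = 1.0,
    min_prominence: float = 0.0,
) -> pd.DataFrame:
    """Per-trial validation metrics.

    Columns: ``movement_time`` (touch - prompt, s),
    ``time_estimation_error`` (|response x scale_max_s - tone_delay|, s),
    ``n_accel_peaks_forward`` / ``n_accel_peaks_backward`` (angular-
    acceleration peak counts within each segment). Metrics whose events
    are missing are NaN, never zero.
    """
    rows = []
    for trial in session.trials:
        et = trial.event_times
        mt = (
            et["touch"] - et["prompt"]
            if "touch" in et and "prompt" in et else np.nan
        )
        if trial.response_value is not None and trial.tone_delay is not None:
            err = abs(trial.response_value * scale_max_s - trial.tone_delay)
        else:
            err = np.nan
        n_fwd = n_bwd = np.nan
        if ang_accel is not None and trial.trial_index in segments:
            fwd, bwd = segments[trial.trial_index]
            # detect over a padded window so the trial's edge peaks keep
            # their flanking minima, then count within each segment span
            pad = int(round(0.40 * ang_accel.fs))
            lo = max(fwd.start - pad, 0)
            hi = min(bwd.end + pad, len(ang_accel))
            piece = TimeSeries(
                t=ang_accel.t[lo:hi], v=ang_accel.v[lo:hi],
                fs=ang_accel.fs, units=ang_accel.units,
            )
            try:
                idx = detect_extrema(piece, min_prominence).peak_idx + lo
            except InputError:
                idx = np.array([], dtype=int)
            n_fwd = int(np.sum((idx >= fwd.start) & (idx < fwd.end)))
            n_bwd = int(np.sum((idx >= bwd.start) & (idx < bwd.end)))
        rows.append(
            {
                "trial": trial.trial_index,
                "condition": trial.condition,
                "movement_time": mt,
                "time_estimation_error": err,
                "n_accel_peaks_forward": n_fwd,
                "n_accel_peaks_backward": n_bwd,
            }
        )
    return pd.DataFrame(rows).set_index("trial")


def paired_condition_test(
    metric_a: np.ndarray, metric_b: np.ndarray
) -> dict[str, float]:
    """Two-sided paired t-test on per-participant means (df = n - 1).

    Returns ``{"t", "df", "p", "degenerate"}``; zero variance of the
    paired differences makes p undefined and sets the degenerate flag.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if len(a) != len(b):
        raise InputError("paired arrays must have equal length")
    if len(a) < 2:
        raise InputError("need at least 2 pairs")
    diff = a - b
    if np.allclose(diff, diff[0]) and not np.allclose(diff, 0):
        return {"t": np.inf, "df": float(len(a) - 1), "p": np.nan,
                "degenerate": True}
    if np.allclose(diff, 0):
        return {"t": 0.0, "df": float(len(a) - 1), "p": 1.0,
                "degenerate": np.allclose(np.std(diff), 0)}
    res = stats.ttest_rel(a, b)
    return {"t": float(res.statistic), "df": float(len(a) - 1),
            "p": float(res.pvalue), "degenerate": False}


def read_trajectory_csv(path, fs: float | None = None) -> Trajectory:
    """Read a trajectory CSV with columns t, x, y, z[, wx, wy, wz | w]."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t", "x", "y", "z"):
        if col not in df.columns:
            raise SpibaError(f"{path}: missing trajectory column {col!r}")
    t = df["t"].to_numpy(dtype=float)
    pos = df[["x", "y", "z"]].to_numpy(dtype=float)
    ang = None
    if {"wx", "wy", "wz"}.issubset(df.columns):
        ang = df[["wx", "wy", "wz"]].to_numpy(dtype=float)
    elif "w" in df.columns:
        ang = df["w"].to_numpy(dtype=float)
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    return Trajectory(t=t, pos=pos, ang_rate=ang, fs=fs)
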