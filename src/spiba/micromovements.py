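"""Micro-movement extraction: alternating extrema and normalized spike trains.

A non-negative biophysical waveform (angular acceleration magnitude,
speed, inter-beat intervals, ...) is reduced to its local peaks and
valleys, and each peak amplitude is mapped into the unit interval by

    AM[i] = peak[i] / (peak[i] + flank_avg[i])

where ``flank_avg[i]`` averages every sample from the left flanking
minimum to the right flanking minimum, inclusive of both endpoints and
of the peak itself. The resulting amplitude micro-movements (AM) are
unit-less, strictly inside (0, 1), and invariant under any positive
rescaling of the waveform, which removes allometric differences between
individuals before distributional estimation.

Timing information is carried by the inter-peak intervals (TM, seconds)
and their normalized counterpart (NTM), obtained by applying the same
normalization to the TM sequence itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import peak_prominences

from .signal_core import InputError, TimeSeries, ValidationError

__all__ = [
    "PeakTrain",
    "MicroMovementSeries",
    "detect_extrema",
    "compute_am",
    "compute_tm",
    "compute_ntm",
    "write_micromovements_csv",
]


@dataclass(frozen=True)
class PeakTrain:
    """Alternating maxima and minima of a waveform.

    Only peaks with both flanking minima are retained, so
    ``len(peak_idx) == len(valley_idx) - 1`` and extrema strictly
    alternate valley, peak, valley, peak, ..., valley.
    """

    peak_idx: np.ndarray      # sample indices of retained local maxima
    valley_idx: np.ndarray    # sample indices of local minima (peaks' flanks)
    peak_amp: np.ndarray      # waveform value at each peak
    flank_avg: np.ndarray     # mean of samples between the flanking minima (incl.)
    peak_times: np.ndarray    # seconds
    units: str = ""

    @property
    def n_peaks(self) -> int:
        return len(self.peak_idx)


@dataclass(frozen=True)
class MicroMovementSeries:
    """Unit-less normalized fluctuations in (0, 1).

    ``kind`` is ``"AM"`` (normalized peak amplitudes) or ``"NTM"``
    (normalized inter-peak timings); ``raw_values`` keeps the underlying
    physical quantities (amplitudes in native units, or TM in seconds)
    and ``raw_median`` their median, used as the color dimension of the
    moments scatter.
    """

    values: np.ndarray
    kind: str
    raw_values: np.ndarray
    peak_times: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != len(self.raw_values):
            raise ValidationError("values and raw_values length mismatch")
        if len(self.values) and not (
            np.all(self.values > 0) and np.all(self.values < 1)
        ):
            raise ValidationError("micro-movement values must lie strictly in (0,1)")

    @property
    def raw_median(self) -> float:
        return float(np.median(self.raw_values)) if len(self.raw_values) else np.nan

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# extrema detection
# ---------------------------------------------------------------------------

def _alternating_extrema(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strictly alternating interior maxima/minima; plateaus -> first sample."""
    d = np.diff(v)
    sign = np.sign(d)
    # carry the next nonzero sign backwards over plateaus so that a
    # plateau extremum is attributed to its first sample
    nz = sign != 0
    if not nz.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    idx = np.where(nz, np.arange(len(sign)), len(sign))
    nxt = np.minimum.accumulate(idx[::-1])[::-1]
    filled = np.where(nxt < len(sign), sign[np.minimum(nxt, len(sign) - 1)], 0)
    # transition points: rising->falling is a max, falling->rising a min
    prev = filled[:-1]
    cur = filled[1:]
    change = (cur != prev) & (prev != 0) & (cur != 0)
    where = np.where(change)[0] + 1  # sample index of the turn
    maxima = where[prev[where - 1] > 0]
    minima = where[prev[where - 1] < 0]
    return maxima, minima


def detect_extrema(
    ts: TimeSeries,
    min_prominence: float = 0.0,
    plateau_rule: str = "first_sample",
) -> PeakTrain:
    """Detect strictly alternating peaks and valleys.

    Boundary samples are never extrema; ties on a plateau go to its first
    sample. ``min_prominence`` (same units as the signal, default 0 so
    every strict sign change counts) removes shallow maxima; alternation
    is re-established afterwards by keeping the lowest valley between
    consecutive retained peaks. The first and last maxima are dropped
    unless they have minima on both sides, since the normalization of
    :func:`compute_am` is undefined without both flanks.
    """
    if plateau_rule != "first_sample":
        raise ValueError(f"unknown plateau_rule {plateau_rule!r}")
    if min_prominence < 0:
        raise ValueError("min_prominence must be >= 0")
    v = np.asarray(ts.v, dtype=float)
    if len(v) < 3:
        raise InputError("need at least 3 samples to detect extrema")

    maxima, minima = _alternating_extrema(v)
    if min_prominence > 0 and len(maxima):
        prom = peak_prominences(v, maxima)[0]
        maxima = maxima[prom >= min_prominence]

    # keep only peaks with a valley on both sides; between consecutive
    # retained peaks keep the single lowest valley
    peaks: list[int] = []
    valleys: list[int] = []
    for pk in maxima:
        left = minima[minima < pk]
        right = minima[minima > pk]
        if len(left) == 0 or len(right) == 0:
            continue
        peaks.append(int(pk))
    peak_arr = np.array(peaks, dtype=int)
    if len(peak_arr):
        # valley before the first peak
        before = minima[minima < peak_arr[0]]
        valleys.append(int(before[np.argmin(v[before])]))
        for a, b in zip(peak_arr[:-1], peak_arr[1:]):
            between = minima[(minima > a) & (minima < b)]
            valleys.append(int(between[np.argmin(v[between])]))
        after = minima[minima > peak_arr[-1]]
        valleys.append(int(after[np.argmin(v[after])]))
    valley_arr = np.array(valleys, dtype=int)

    flank_avg = np.array([
        float(np.mean(v[valley_arr[i]: valley_arr[i + 1] + 1]))
        for i in range(len(peak_arr))
    ])
    return PeakTrain(
        peak_idx=peak_arr,
        valley_idx=valley_arr,
        peak_amp=v[peak_arr] if len(peak_arr) else np.array([]),
        flank_avg=flank_avg,
        peak_times=ts.t[peak_arr] if len(peak_arr) else np.array([]),
        units=ts.units,
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def compute_am(pt: PeakTrain) -> MicroMovementSeries:
    """Amplitude micro-movements: peak / (peak + min-to-min window average).

    Requires a non-negative magnitude waveform (speed, angular
    acceleration magnitude, IBI); raises on negative peaks or flanks.
    Peaks with a zero denominator are dropped with a warning.
    """
    if pt.n_peaks == 0:
        return MicroMovementSeries(
            values=np.array([]), kind="AM", raw_values=np.array([]),
            peak_times=np.array([]), units=pt.units,
        )
    if np.any(pt.peak_amp < 0) or np.any(pt.flank_avg < 0):
        raise ValidationError(
            "amplitude normalization requires a non-negative magnitude waveform"
        )
    denom = pt.peak_amp + pt.flank_avg
    keep = denom > 0
    if not keep.all():
        warnings.warn(
            f"dropped {int((~keep).sum())} peak(s) with zero denominator",
            stacklevel=2,
        )
    values = pt.peak_amp[keep] / denom[keep]
    return MicroMovementSeries(
        values=values,
        kind="AM",
        raw_values=pt.peak_amp[keep],
        peak_times=pt.peak_times[keep],
        units=pt.units,
    )


def compute_tm(pt: PeakTrain) -> np.ndarray:
    """Inter-peak intervals in seconds; empty (with warning) for < 2 peaks."""
    if pt.n_peaks < 2:
        warnings.warn("fewer than 2 peaks: empty TM series", stacklevel=2)
        return np.array([])
    return np.diff(pt.peak_times)


def compute_ntm(
    tm: np.ndarray,
    mode: str = "series_minima",
    peak_times: np.ndarray | None = None,
) -> MicroMovementSeries:
    """Timing micro-movements: the amplitude normalization applied to TM.

    ``series_minima`` (default) treats the TM sequence as a discrete
    signal, finds its own local maxima/minima and normalizes each TM
    local peak by the flanking-minima window average — the literal reuse
    of the amplitude rule on the timing array. ``global_mean`` maps every
    interval through ``tm[i] / (tm[i] + mean(tm))``. Both are invariant
    under rescaling of the intervals.
    """
    tm = np.asarray(tm, dtype=float)
    if peak_times is None:
        peak_times = np.arange(len(tm), dtype=float)
    peak_times = np.asarray(peak_times, dtype=float)[: len(tm)]

    if mode == "global_mean":
        if len(tm) < 1:
            raise InputError("global_mean normalization needs >= 1 interval")
        values = tm / (tm + np.mean(tm))
        return MicroMovementSeries(
            values=values, kind="NTM", raw_values=tm,
            peak_times=peak_times, units="s",
        )
    if mode != "series_minima":
        raise ValueError(f"unknown NTM mode {mode!r}")

    if len(tm) < 3:
        raise InputError("series_minima normalization needs >= 3 intervals")
    maxima, minima = _alternating_extrema(tm)
    if len(maxima) == 0:
        warnings.warn(
            "TM sequence has no interior extrema: empty NTM series", stacklevel=2
        )
        return MicroMovementSeries(
            values=np.array([]), kind="NTM", raw_values=np.array([]),
            peak_times=np.array([]), units="s",
        )
    # the TM sequence is short and discrete: its endpoints may serve as
    # flanking minima, and the peak itself is excluded from the window
    # average (only the values surrounding the TM peak enter the
    # denominator)
    if len(minima) == 0 or minima[0] > maxima[0]:
        minima = np.concatenate([[0], minima])
    if minima[-1] < maxima[-1]:
        minima = np.concatenate([minima, [len(tm) - 1]])
    values, raw, times = [], [], []
    for pk in maxima:
        left = minima[minima < pk]
        right = minima[minima > pk]
        if len(left) == 0 or len(right) == 0:
            continue
        l, r = int(left[-1]), int(right[0])
        window = np.concatenate([tm[l:pk], tm[pk + 1: r + 1]])
        denom = tm[pk] + float(np.mean(window))
        if denom <= 0:
            continue
        values.append(tm[pk] / denom)
        raw.append(tm[pk])
        times.append(peak_times[pk] if pk < len(peak_times) else float(pk))
    return MicroMovementSeries(
        values=np.array(values), kind="NTM", raw_values=np.array(raw),
        peak_times=np.array(times), units="s",
    )


def write_micromovements_csv(mm: MicroMovementSeries, path) -> None:
    """Columns: peak_time_s, raw_value, mm_value, kind, units."""
    pd.DataFrame(
        {
            "peak_time_s": mm.peak_times,
            "raw_value": mm.raw_values,
            "mm_value": mm.values,
            "kind": mm.kind,
            "units": mm.units,
        }
    ).to_csv(path, index=False, float_format="%.17g")
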