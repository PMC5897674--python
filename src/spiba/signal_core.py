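"""Core data model: uniformly sampled time series, trial records, sessions.

Conventions used throughout the package:

* time is in seconds, sample indexing is 0-based;
* segments are half-open ``[start, end)`` intervals in sample indices;
* CSV files are comma-separated UTF-8 with a header row and decimal points.

A :class:`TimeSeries` is accepted only if its time base is uniform to
within 1% of the sampling interval; files beyond that tolerance are
rejected rather than silently resampled, because the derivative
estimators downstream assume uniform sampling.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("spiba")

#: Relative tolerance on |dt - 1/fs| for a series to count as uniform.
UNIFORM_TOL = 0.01

#: Schema version stamped into every JSON report.
REPORT_SCHEMA_VERSION = "1.0"


class SpibaError(Exception):
    """Base class for all package errors."""


class FormatError(SpibaError):
    """A file does not follow the documented CSV layout."""


class ValidationError(SpibaError):
    """Data violate a structural invariant (monotonic time, NaNs, ...)."""


class InputError(SpibaError):
    """An operation received input it cannot work with (too short, empty)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing, uniform within
        ``UNIFORM_TOL`` of ``1/fs``.
    v : ndarray
        Sample values in the physical units given by ``units``.
    fs : float
        Sampling rate in Hz.
    channel_id : str
        Free-text channel label (e.g. ``"ecg"``, ``"ang_rate"``).
    units : str
        Free-text physical units label (e.g. ``"mV"``, ``"deg/s^2"``).
    """

    t: np.ndarray
    v: np.ndarray
    fs: float
    channel_id: str = "signal"
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        if self.t.ndim != 1 or self.v.ndim != 1:
            raise ValidationError("t and v must be 1-D arrays")
        if len(self.t) != len(self.v):
            raise ValidationError(
                f"length mismatch: t has {len(self.t)}, v has {len(self.v)}"
            )
        if not (self.fs > 0):
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValidationError("time base is not strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fs)) > UNIFORM_TOL / self.fs:
                raise ValidationError(
                    "non-uniform sampling: max |dt - 1/fs| exceeds 1% of the "
                    "sampling interval; resample before loading"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0


@dataclass(frozen=True)
class TrialRecord:
    """Events of one pointing trial.

    ``event_times`` holds the prompt/touch/tone/response times in seconds
    (keys may be absent when an event was not recorded); events must be
    non-decreasing in the order prompt <= touch <= tone <= response, and
    ``tone - touch`` must equal ``tone_delay`` within one sample at the
    session's kinematic rate.
    """

    trial_index: int
    condition: str
    event_times: Mapping[str, float]
    tone_delay: float | None = None
    response_value: float | None = None

    _EVENT_ORDER = ("prompt", "touch", "tone", "response")

    def __post_init__(self) -> None:
        if self.trial_index < 0:
            raise ValidationError("trial_index must be >= 0")
        present = [
            (k, self.event_times[k])
            for k in self._EVENT_ORDER
            if k in self.event_times and self.event_times[k] is not None
        ]
        times = [v for _, v in present]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"trial {self.trial_index}: event times out of order {present}"
            )
        if self.response_value is not None and not (0.0 <= self.response_value <= 1.0):
            raise ValidationError("response_value must lie in [0, 1]")

    def check_tone_delay(self, fs: float) -> None:
        """Verify tone - touch == tone_delay within one sample at rate fs."""
        et = self.event_times
        if self.tone_delay is None or "tone" not in et or "touch" not in et:
            return
        if abs((et["tone"] - et["touch"]) - self.tone_delay) > 1.0 / fs:
            raise ValidationError(
                f"trial {self.trial_index}: tone-touch interval "
                f"{et['tone'] - et['touch']:.4f}s != tone_delay {self.tone_delay}s"
            )


@dataclass
class SessionRecord:
    """One participant x condition block of trials plus its signal channels."""

    participant_id: str
    condition: str
    trials: list[TrialRecord]
    channels: dict[str, TimeSeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.trials) < 1:
            raise ValidationError("a session needs at least one trial")
        for ch in self.channels.values():
            t0, t1 = ch.t[0], ch.t[-1]
            for trial in self.trials:
                for name, when in trial.event_times.items():
                    if when is not None and not (t0 - 1e-9 <= when <= t1 + 1e-9):
                        raise ValidationError(
                            f"trial {trial.trial_index} event {name}={when}s outside "
                            f"channel '{ch.channel_id}' range [{t0}, {t1}]s"
                        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_timeseries_csv(
    path: str | Path,
    column_spec: Mapping[str, str] | None = None,
    fs: float | None = None,
    channel_id: str | None = None,
    units: str = "",
    sep: str = ",",
) -> TimeSeries:
    """Read a single-channel time series from CSV.

    ``column_spec`` maps column names to roles ``{"time", "value"}``;
    by default the columns ``time_s`` and ``value`` are used. When the
    file has no time column, ``fs`` must be given and the time base is
    synthesized as ``k / fs`` from ``k = 0``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        # round_trip parsing: 17-significant-digit CSVs reproduce the
        # exact binary doubles that were written
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty file: {path}") from exc
    if len(df) < 2:
        raise InputError(f"{path}: need at least 2 rows, got {len(df)}")

    spec = dict(column_spec or {})
    time_col = next((c for c, r in spec.items() if r == "time"), None)
    value_col = next((c for c, r in spec.items() if r == "value"), None)
    if value_col is None:
        value_col = "value" if "value" in df.columns else None
    if time_col is None and "time_s" in df.columns:
        time_col = "time_s"
    if value_col is None or value_col not in df.columns:
        raise FormatError(f"{path}: missing value column {value_col or 'value'!r}")

    v = df[value_col].to_numpy(dtype=float)
    if time_col is not None:
        if time_col not in df.columns:
            raise FormatError(f"{path}: missing time column {time_col!r}")
        t = df[time_col].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"{path}: time column is not strictly increasing")
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(t)))
    else:
        if fs is None:
            raise FormatError(
                f"{path}: no time column and no sampling rate declared"
            )
        t = np.arange(len(v)) / fs
    return TimeSeries(t=t, v=v, fs=float(fs), channel_id=channel_id or value_col,
                      units=units)


def write_timeseries_csv(ts: TimeSeries, path: str | Path) -> Path:
    """Write a TimeSeries as ``time_s,value`` CSV at full float precision."""
    path = Path(path)
    df = pd.DataFrame({"time_s": ts.t, "value": ts.v})
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_trial_events_csv(path: str | Path) -> list[TrialRecord]:
    """Read a trial-event table.

    Expected columns: ``trial, condition, t_prompt, t_touch, t_tone,
    t_response[, tone_delay, response_value]``; missing event cells may be
    left blank.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"trial", "condition"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    trials = []
    for _, row in df.iterrows():
        events = {}
        for name in ("prompt", "touch", "tone", "response"):
            col = f"t_{name}"
            if col in df.columns and pd.notna(row[col]):
                events[name] = float(row[col])
        trials.append(
            TrialRecord(
                trial_index=int(row["trial"]),
                condition=str(row["condition"]),
                event_times=events,
                tone_delay=float(row["tone_delay"])
                if "tone_delay" in df.columns and pd.notna(row["tone_delay"])
                else None,
                response_value=float(row["response_value"])
                if "response_value" in df.columns and pd.notna(row["response_value"])
                else None,
            )
        )
    return trials


def write_trial_events_csv(trials: list[TrialRecord], path: str | Path) -> Path:
    rows = []
    for tr in trials:
        row: dict[str, Any] = {"trial": tr.trial_index, "condition": tr.condition}
        for name in ("prompt", "touch", "tone", "response"):
            row[f"t_{name}"] = tr.event_times.get(name)
        row["tone_delay"] = tr.tone_delay
        row["response_value"] = tr.response_value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return Path(path)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationReport:
    n_samples: int
    n_interpolated: int
    warnings: tuple[str, ...] = ()


def validate_timeseries(
    ts: TimeSeries, nan_policy: str = "reject"
) -> tuple[TimeSeries, ValidationReport]:
    """Apply the NaN policy and return the cleaned series plus a report.

    Under ``interpolate``, interior NaNs are linearly interpolated on the
    time base and counted; leading or trailing NaNs cannot be interpolated
    and raise. Under ``reject`` any NaN raises. Idempotent: validating an
    already-valid series returns it unchanged.
    """
    if len(ts) == 0:
        raise InputError("empty time series")
    bad = ~np.isfinite(ts.v)
    if not bad.any():
        return ts, ValidationReport(n_samples=len(ts), n_interpolated=0)
    if nan_policy == "reject":
        raise ValidationError(f"{int(bad.sum())} non-finite samples in "
                              f"channel '{ts.channel_id}'")
    if nan_policy != "interpolate":
        raise ValueError(f"unknown nan_policy {nan_policy!r}")
    if bad[0] or bad[-1]:
        raise ValidationError("leading/trailing NaNs cannot be interpolated")
    v = ts.v.copy()
    good = ~bad
    v[bad] = np.interp(ts.t[bad], ts.t[good], v[good])
    report = ValidationReport(n_samples=len(ts), n_interpolated=int(bad.sum()))
    return replace(ts, v=v), report


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------

def _jsonify(obj: Any, warn: list[str], path: str = "") -> Any:
    """Convert to JSON-serializable form; non-finite floats become null."""
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        if not math.isfinite(x):
            warn.append(f"non-finite value at {path or 'root'} serialized as null")
            return None
        return x
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(x, warn, f"{path}[{i}]") for i, x in enumerate(obj.tolist())]
    if isinstance(obj, (list, tuple)):
        return [_jsonify(x, warn, f"{path}[{i}]") for i, x in enumerate(obj)]
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v, warn, f"{path}.{k}") for k, v in obj.items()}
    if hasattr(obj, "__dataclass_fields__"):
        return {
            k: _jsonify(getattr(obj, k), warn, f"{path}.{k}")
            for k in obj.__dataclass_fields__
        }
    if obj is None or isinstance(obj, str):
        return obj
    return str(obj)


def config_hash(params: Mapping[str, Any] | None) -> str:
    """Stable short hash of a parameter mapping, for provenance stamps."""
    blob = json.dumps(_jsonify(dict(params or {}), []), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_report_json(
    results: Any,
    path: str | Path,
    *,
    params: Mapping[str, Any] | None = None,
    seed: int | None = None,
) -> Path:
    """Serialize a fit/comparison structure to JSON with provenance.

    The envelope records the schema version, the parameter mapping and its
    hash, and the seed. Non-finite numbers (e.g. CIs of a degenerate fit)
    are written as ``null`` and flagged in ``warnings``.
    """
    path = Path(path)
    warn: list[str] = []
    body = _jsonify(results, warn)
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "parameters": _jsonify(dict(params or {}), warn, "parameters"),
        "provenance": {"seed": seed, "config_hash": config_hash(params)},
        "warnings": warn,
        "results": body,
    }
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)
    except OSError as exc:
        raise SpibaError(f"cannot write report to {path}: {exc}") from exc
    if warn:
        warnings.warn("; ".join(warn), stacklevel=2)
    return path


def read_report_json(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
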