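"""Ground-truthed synthetic sessions: pointing kinematics and ECG.

The generator emulates the structure of a cognitive-load pointing study:
three conditions (control, low load, high load) of 60 trials each, every
trial an out-and-back pointing motion of about 1.5 s recorded at 240 Hz,
plus a continuous ECG channel at 256 Hz whose inter-beat intervals
follow a Gamma law.

Kinematics
----------
Each trial renders a minimum-jerk reach from the rest position to the
target and back (bell-shaped speed, a single interior speed maximum per
segment, zero velocity at the turnaround where the hand-to-target
distance is minimal). The angular-rate channel is built so that the
derived angular-acceleration magnitude carries planted spike structure:
compact sech^2 acceleration bumps whose peak amplitudes are i.i.d. draws
from the condition's Gamma law and whose inter-peak gaps follow a
Gamma law of their own (clipped below so neighboring bumps never merge).
Bump signs alternate toward a positive baseline so the angular rate
stays a strictly positive magnitude signal. Higher-load presets plant
denser peak trains and slower reaches.

ECG
---
Beat times accumulate Gamma-distributed inter-beat intervals; each beat
is rendered as a biphasic difference-of-Gaussians QRS-like template with
80 ms support (spectral content inside the 5-30 Hz detection band), with
optional white noise at a given SNR and 0.3 Hz baseline wander.

Every dataset is reproducible from (config, seed) alone; the planted
truth (bump times/amplitudes, per-segment peak counts, split indices,
beat times) is returned alongside the data and can be serialized next
to any exported dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .kinematics import Trajectory
from .signal_core import SessionRecord, SpibaError, TimeSeries, TrialRecord

__all__ = [
    "GroundTruth",
    "CONDITION_PRESETS",
    "simulate_pointing_session",
    "simulate_ecg",
    "make_cohort",
    "session_trajectory",
]

#: Per-condition presets: Gamma law of the planted angular-acceleration
#: peak amplitudes (deg/s^2), mean inter-bump gap (s), forward-reach
#: duration (s). Higher load -> denser peaks and slower reaches.
CONDITION_PRESETS: dict[str, dict[str, Any]] = {
    "control": {"gamma": (3.0, 60.0), "gap_mean": 0.185, "forward_s": 0.70},
    "low_load": {"gamma": (2.5, 80.0), "gap_mean": 0.165, "forward_s": 0.75},
    "high_load": {"gamma": (2.0, 120.0), "gap_mean": 0.145, "forward_s": 0.90},
}

#: sech^2 acceleration-bump width parameter (s); FWHM ~ 3.5x this.
BUMP_WIDTH_S = 0.020
#: Physiological tremor floor: acceleration amplitude relative to the
#: planted Gamma mean, at 8 Hz. Keeps rest periods from being perfectly
#: flat (no real sensor is) and guarantees flanking minima around every
#: planted peak; it sits far below any peak-detection prominence floor.
TREMOR_FRAC = 0.001
TREMOR_HZ = 8.0
#: Gaps are clipped below this (s) so neighboring bumps stay separable.
MIN_GAP_S = 0.140
#: Shape of the Gamma law the inter-bump gaps are drawn from.
GAP_SHAPE = 4.0

TRIAL_S = 3.0          # one trial's slot in the continuous recording
PROMPT_REL_S = 0.2     # prompt time within the trial slot
REACTION_S = 0.3       # prompt -> movement onset
TONE_DELAYS = (0.1, 0.4, 0.7)

DEFAULT_TARGET = np.array([0.0, 30.0, 10.0])   # cm, rest at the origin


@dataclass
class GroundTruth:
    """Planted truth that fully determines a regenerated dataset."""

    seed: int
    params: dict[str, Any] = field(default_factory=dict)
    trials: list[dict[str, Any]] = field(default_factory=list)
    beat_times: np.ndarray | None = None
    ibi: np.ndarray | None = None

    @property
    def all_bump_amps(self) -> np.ndarray:
        return np.concatenate([tr["bump_amps"] for tr in self.trials]) \
            if self.trials else np.array([])

    def bump_amps(self, kind: str) -> np.ndarray:
        """Planted amplitudes in the forward or backward segments."""
        out = []
        for tr in self.trials:
            mask = tr["bump_forward"] if kind == "forward" else ~tr["bump_forward"]
            out.append(tr["bump_amps"][mask])
        return np.concatenate(out) if out else np.array([])

    def to_dict(self) -> dict[str, Any]:
        doc: dict[str, Any] = {"seed": self.seed, "params": self.params}
        if self.trials:
            doc["trials"] = [
                {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in tr.items()}
                for tr in self.trials
            ]
        if self.beat_times is not None:
            doc["beat_times"] = self.beat_times.tolist()
            doc["ibi"] = self.ibi.tolist()
        return doc


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on tau in [0, 1]."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _render_reach(
    t_rel: np.ndarray, start: float, dur: float, back: bool
) -> np.ndarray:
    """Fraction of the rest->target path covered at each time."""
    tau = np.clip((t_rel - start) / dur, 0.0, 1.0)
    frac = _min_jerk(tau)
    return 1.0 - frac if back else frac


def simulate_pointing_session(
    n_trials: int = 60,
    condition: str = "control",
    gamma_params: tuple[float, float] | None = None,
    fs: float = 240.0,
    movement_s: float | None = None,
    seed: int = 0,
    participant_id: str = "sim",
    gap_mean: float | None = None,
    target_pos: np.ndarray = DEFAULT_TARGET,
    response_noise_sd: float = 0.08,
) -> tuple[SessionRecord, GroundTruth]:
    """Simulate one participant x condition block of pointing trials.

    ``gamma_params`` is the (shape, scale) law of the planted
    angular-acceleration peak amplitudes; ``movement_s`` the total
    out-and-back movement duration (default ~1.5 s, split between the
    condition's forward duration and the retraction); ``gap_mean`` the
    mean inter-bump gap. Unset values come from ``CONDITION_PRESETS``.
    """
    preset = CONDITION_PRESETS.get(condition, CONDITION_PRESETS["control"])
    a, b = gamma_params if gamma_params is not None else preset["gamma"]
    if not (a > 0 and b > 0):
        raise SpibaError("gamma shape/scale must be positive")
    gap_mean = gap_mean if gap_mean is not None else preset["gap_mean"]
    if gap_mean < MIN_GAP_S / 2:
        raise SpibaError(
            f"mean gap {gap_mean}s infeasible: bumps of width {BUMP_WIDTH_S}s "
            "cannot be resolved that densely"
        )
    forward_s = preset["forward_s"]
    backward_s = (movement_s - forward_s) if movement_s else 0.75
    if backward_s <= 0.2:
        raise SpibaError("movement_s too short for the forward duration")

    rng = np.random.default_rng(seed)
    n_samples = int(round(n_trials * TRIAL_S * fs))
    t = np.arange(n_samples) / fs
    target = np.asarray(target_pos, dtype=float)

    frac = np.zeros(n_samples)            # fraction of rest->target path
    acc_signed = np.zeros(n_samples)      # planted angular acceleration
    w = BUMP_WIDTH_S
    half_support = int(round(10 * w * fs))
    sup = np.arange(-half_support, half_support + 1)
    bump_shape = 1.0 / np.cosh(sup / (2 * w * fs)) ** 2

    trials: list[TrialRecord] = []
    truth_trials: list[dict[str, Any]] = []
    for k in range(n_trials):
        t0 = k * TRIAL_S
        prompt = t0 + PROMPT_REL_S
        onset_t = prompt + REACTION_S
        touch = onset_t + forward_s
        offset_t = touch + backward_s
        tone_delay = float(rng.choice(TONE_DELAYS))
        tone = touch + tone_delay
        # response comes after the hand is back at rest
        response = max(tone + 0.6, offset_t + 0.2)
        resp_val = float(np.clip(
            tone_delay / 1.0 + rng.normal(0.0, response_noise_sd), 0.0, 1.0
        ))

        sl = slice(int(round(t0 * fs)), int(round((t0 + TRIAL_S) * fs)))
        t_rel = t[sl] - t0
        fwd = _render_reach(t_rel, onset_t - t0, forward_s, back=False)
        inmove = t[sl] >= touch
        bwd = _render_reach(t_rel, touch - t0, backward_s, back=True)
        frac[sl] = np.where(inmove, bwd, fwd)

        # plant acceleration bumps inside the movement window
        bump_t = []
        cursor = onset_t + 0.06
        while True:
            gap = max(rng.gamma(GAP_SHAPE, gap_mean / GAP_SHAPE), MIN_GAP_S)
            nxt = cursor + gap if bump_t else cursor
            if nxt > offset_t - 0.06:
                break
            # keep bumps clearly on one side of the turnaround so the
            # planted forward/backward assignment is unambiguous
            if abs(nxt - touch) < 0.025:
                nxt = touch + 0.025
            bump_t.append(nxt)
            cursor = nxt
        bump_idx = np.round(np.array(bump_t) * fs).astype(int)
        bump_t_snap = bump_idx / fs
        amps = rng.gamma(a, b, size=len(bump_idx))
        # alternate bump signs toward a positive baseline so the angular
        # rate never crosses zero
        level = 0.0
        signs = np.empty(len(bump_idx))
        for i in range(len(bump_idx)):
            signs[i] = -1.0 if level > 0 else 1.0
            level += signs[i] * 4 * w * amps[i]
        for idx, amp, sgn in zip(bump_idx, amps, signs):
            lo = max(idx - half_support, 0)
            hi = min(idx + half_support + 1, n_samples)
            acc_signed[lo:hi] += sgn * amp * bump_shape[
                lo - (idx - half_support): hi - (idx - half_support)
            ]

        split_idx = int(round(touch * fs))
        trials.append(
            TrialRecord(
                trial_index=k,
                condition=condition,
                event_times={"prompt": prompt, "touch": touch,
                             "tone": tone, "response": response},
                tone_delay=tone_delay,
                response_value=resp_val,
            )
        )
        truth_trials.append(
            {
                "trial_index": k,
                "bump_times": bump_t_snap,
                "bump_idx": bump_idx,
                "bump_amps": amps,
                "bump_forward": bump_idx < split_idx,
                "n_peaks_forward": int(np.sum(bump_idx < split_idx)),
                "n_peaks_backward": int(np.sum(bump_idx >= split_idx)),
                "split_idx": split_idx,
                "onset_idx": int(round(onset_t * fs)),
                "offset_idx": int(round(offset_t * fs)),
                "tone_delay": tone_delay,
            }
        )

    pos = np.outer(frac, target)
    acc_signed += TREMOR_FRAC * a * b * np.sin(
        2 * np.pi * TREMOR_HZ * t + rng.uniform(0, 2 * np.pi)
    )
    # integrate the planted acceleration and lift it onto a positive
    # baseline so |angular rate| == angular rate
    ang_rate = np.cumsum(acc_signed) / fs
    baseline = 1.05 * max(float(np.max(np.abs(ang_rate))), 1e-9)
    ang_rate = ang_rate + baseline

    channels = {
        "pos_x": TimeSeries(t=t, v=pos[:, 0], fs=fs, channel_id="pos_x", units="cm"),
        "pos_y": TimeSeries(t=t, v=pos[:, 1], fs=fs, channel_id="pos_y", units="cm"),
        "pos_z": TimeSeries(t=t, v=pos[:, 2], fs=fs, channel_id="pos_z", units="cm"),
        "ang_rate": TimeSeries(t=t, v=ang_rate, fs=fs, channel_id="ang_rate",
                               units="deg/s"),
    }
    session = SessionRecord(
        participant_id=participant_id, condition=condition,
        trials=trials, channels=channels,
    )
    truth = GroundTruth(
        seed=seed,
        params={
            "condition": condition, "gamma": (a, b), "gap_mean": gap_mean,
            "fs": fs, "n_trials": n_trials, "forward_s": forward_s,
            "backward_s": backward_s, "target_pos": target.tolist(),
        },
        trials=truth_trials,
    )
    return session, truth


def session_trajectory(session: SessionRecord) -> Trajectory:
    """Assemble the Trajectory view of a simulated session's channels."""
    t = session.channels["pos_x"].t
    pos = np.column_stack([
        session.channels["pos_x"].v,
        session.channels["pos_y"].v,
        session.channels["pos_z"].v,
    ])
    ang = session.channels.get("ang_rate")
    return Trajectory(t=t, pos=pos,
                      ang_rate=ang.v if ang is not None else None,
                      fs=session.channels["pos_x"].fs)


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def _qrs_template(fs: float, support_s: float = 0.080) -> np.ndarray:
    """Biphasic difference-of-Gaussians QRS-like pulse, unit R amplitude."""
    half = int(round(support_s / 2 * fs))
    tt = np.arange(-half, half + 1) / fs
    s1, s2, k = 0.008, 0.020, 0.4
    g = np.exp(-tt**2 / (2 * s1**2)) - k * np.exp(-tt**2 / (2 * s2**2))
    return g / g[half]


def simulate_ecg(
    duration_s: float,
    ibi_gamma: tuple[float, float] | None = (40.0, 0.02),
    fs: float = 256.0,
    snr_db: float | None = None,
    baseline_amp: float = 0.0,
    baseline_hz: float = 0.3,
    seed: int = 0,
    ibi_constant: float | None = None,
) -> tuple[TimeSeries, GroundTruth]:
    """Simulate an ECG channel with known beat times.

    Inter-beat intervals are drawn from Gamma ``ibi_gamma`` (shape x
    scale = mean IBI, which must lie in [0.3, 2.0] s) or held constant at
    ``ibi_constant``. Each beat is a narrow biphasic QRS-like template;
    ``snr_db`` adds white noise at that signal-to-noise ratio and
    ``baseline_amp`` a 0.3 Hz baseline wander. Planted beat times are
    snapped to the sample grid and recorded in the ground truth.
    """
    if fs <= 60:
        raise SpibaError("ECG sampling rate must exceed 60 Hz")
    rng = np.random.default_rng(seed)
    if ibi_constant is not None:
        mean_ibi = ibi_constant
    else:
        a, b = ibi_gamma
        mean_ibi = a * b
    if not (0.3 <= mean_ibi <= 2.0):
        raise SpibaError(f"mean IBI {mean_ibi:.3f}s outside [0.3, 2.0]s")

    beats = []
    t_beat = 0.5
    while t_beat < duration_s - 0.3:
        beats.append(t_beat)
        ibi = ibi_constant if ibi_constant is not None else rng.gamma(a, b)
        t_beat += max(ibi, 0.2)
    beat_idx = np.round(np.array(beats) * fs).astype(int)
    beat_times = beat_idx / fs

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    v = np.zeros(n)
    tmpl = _qrs_template(fs)
    half = len(tmpl) // 2
    for idx in beat_idx:
        lo, hi = max(idx - half, 0), min(idx + half + 1, n)
        v[lo:hi] += tmpl[lo - (idx - half): hi - (idx - half)]

    clean_power = float(np.mean(v**2))
    if baseline_amp:
        v = v + baseline_amp * np.sin(
            2 * np.pi * baseline_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if snr_db is not None:
        sigma = np.sqrt(clean_power / 10 ** (snr_db / 10.0))
        v = v + rng.normal(0.0, sigma, size=n)

    ts = TimeSeries(t=t, v=v, fs=fs, channel_id="ecg", units="mV")
    truth = GroundTruth(
        seed=seed,
        params={
            "duration_s": duration_s, "fs": fs, "ibi_gamma": ibi_gamma,
            "ibi_constant": ibi_constant, "snr_db": snr_db,
            "baseline_amp": baseline_amp, "baseline_hz": baseline_hz,
        },
        beat_times=beat_times,
        ibi=np.diff(beat_times),
    )
    return ts, truth


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def make_cohort(
    n_participants: int = 9,
    conditions: tuple[str, ...] = ("control", "low_load", "high_load"),
    shape_range: tuple[float, float] = (1.5, 4.0),
    scale_center: float = 80.0,
    scale_spread: float = 0.3,
    equal_mean: float | None = None,
    n_trials: int = 60,
    seed: int = 0,
) -> tuple[list[tuple[SessionRecord, GroundTruth]], GroundTruth]:
    """Simulate a cohort of participants with between-participant spread.

    Per participant x condition, the amplitude-law shape is drawn
    uniformly from ``shape_range``; the scale is either drawn around
    ``scale_center`` (log-uniform within ``+-scale_spread`` in log units)
    or, when ``equal_mean`` is given, constrained to ``equal_mean /
    shape`` so every law shares the same mean — the configuration under
    which the Gamma-plane log-log fit has slope exactly -1.
    """
    rng = np.random.default_rng(seed)
    sessions: list[tuple[SessionRecord, GroundTruth]] = []
    draws: list[dict[str, Any]] = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        for cond in conditions:
            a = float(rng.uniform(*shape_range))
            if equal_mean is not None:
                b = equal_mean / a
            else:
                b = float(scale_center * np.exp(
                    rng.uniform(-scale_spread, scale_spread)
                ))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            sess, truth = simulate_pointing_session(
                n_trials=n_trials, condition=cond, gamma_params=(a, b),
                seed=sub_seed, participant_id=pid,
            )
            sessions.append((sess, truth))
            draws.append({"participant_id": pid, "condition": cond,
                          "shape": a, "scale": b, "seed": sub_seed})
    cohort_truth = GroundTruth(
        seed=seed,
        params={
            "n_participants": n_participants, "conditions": list(conditions),
            "equal_mean": equal_mean, "draws": draws,
        },
    )
    return sessions, cohort_truth
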