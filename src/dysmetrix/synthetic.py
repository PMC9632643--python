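"""Synthetic binocular horizontal-saccade recordings.

Emulates the standard clinical horizontal-saccade task: a target starts at
the screen center, jumps 16 degrees to the left or right, dwells there for a
uniformly distributed 1.3-2.0 s, and returns to center, for a pseudorandom
sequence of trials.  The simulated eye follows the target with a reaction
latency, executing a smooth main-sequence saccade whose amplitude is a
per-saccade *gain* times the target displacement:

* control subjects have gain near 1 (healthy saccades slightly undershoot),
* hypometric dysmetria means gain well below 1 followed by a corrective
  saccade in the same direction,
* hypermetric dysmetria means gain above 1 (overshoot) followed by a return
  toward the target,
* mixed dysmetria draws each saccade's gain from a hypo/hyper mixture.

Blinks are inserted as brief large excursions that return to the pre-blink
level, plus slow sinusoidal drift and additive white measurement noise.  The
right-eye channel shares the saccade events of the left eye but carries
independent noise and a per-saccade gain perturbation, so the two channels
are strongly but imperfectly coupled.

Amplitudes are in raw "normalized iris center" (NIC) units; the +/-16 degree
targets map linearly to +/-0.4 raw units (downstream range normalization
removes absolute scale, only linearity matters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

DEG_TO_NIC = 0.025  # 16 deg -> 0.4 raw NIC units

#: main-sequence rule for saccade duration: ~2.2 ms per degree + 21 ms
MS_SLOPE_S_PER_DEG = 0.0022
MS_INTERCEPT_S = 0.021


@dataclass(frozen=True)
class TargetSchedule:
    """Stimulus sequence of the saccade task.

    ``onset_times`` holds the time of every target jump (two per trial:
    center -> periphery and periphery -> center); ``dwell_durations`` the
    dwell following each jump.
    """

    trial_directions: tuple  # "left" / "right" per trial
    onset_times: np.ndarray  # seconds, one per target jump (2 per trial)
    dwell_durations: np.ndarray  # seconds, one per target jump
    amplitude_deg: float

    @property
    def n_trials(self) -> int:
        return len(self.trial_directions)

    @property
    def n_jumps(self) -> int:
        return len(self.onset_times)

    def target_positions(self) -> np.ndarray:
        """Target position in raw NIC units after each jump."""
        amp = self.amplitude_deg * DEG_TO_NIC
        pos = []
        for d in self.trial_directions:
            side = -amp if d == "left" else amp
            pos.extend([side, 0.0])
        return np.asarray(pos)

    def to_dict(self) -> dict:
        return {
            "trial_directions": list(self.trial_directions),
            "onset_times": self.onset_times.tolist(),
            "dwell_durations": self.dwell_durations.tolist(),
            "amplitude_deg": self.amplitude_deg,
        }


@dataclass
class SubjectProfile:
    """Generative parameters of one synthetic subject."""

    group_label: str = "control"  # "control" | "dysmetric"
    primary_gain_mean: float = 0.95
    primary_gain_sd: float = 0.02
    dysmetria_mode: str = "none"  # none | hypometric | hypermetric | mixed
    corrective_latency_mean: float = 0.15  # s after primary saccade end
    corrective_gain: float = 0.85  # fraction of remaining error corrected
    blink_rate: float = 12.0  # events / minute
    drift_amplitude: float = 0.02  # raw NIC units
    noise_sd: float = 0.01  # raw NIC units
    #: disconjugacy scale: per-saccade right-eye gain jitter (fractional) and
    #: onset-time jitter (sd = 0.5 * asymmetry seconds)
    left_right_asymmetry: float = 0.01
    # second mixture component mean for dysmetria_mode == "mixed"
    mixed_gain_means: tuple = (0.72, 1.25)

    def __post_init__(self):
        for name in ("primary_gain_sd", "blink_rate", "drift_amplitude",
                     "noise_sd", "left_right_asymmetry",
                     "corrective_latency_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.group_label == "control":
            if self.dysmetria_mode != "none":
                raise ValueError("control profiles must have dysmetria_mode='none'")
            if not (0.90 <= self.primary_gain_mean <= 0.98):
                raise ValueError("control primary_gain_mean must lie in [0.90, 0.98]")
        if self.dysmetria_mode == "hypometric" and self.primary_gain_mean >= 0.85:
            raise ValueError("hypometric profiles require primary_gain_mean < 0.85")
        if self.dysmetria_mode == "hypermetric" and self.primary_gain_mean <= 1.10:
            raise ValueError("hypermetric profiles require primary_gain_mean > 1.10")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mixed_gain_means"] = list(self.mixed_gain_means)
        return d


@dataclass
class GazeRecording:
    """Binocular horizontal gaze trace."""

    fs: float
    duration: float
    left_x: np.ndarray
    right_x: np.ndarray
    label: str | None = None
    schedule: TargetSchedule | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = int(round(self.fs * self.duration))
        if len(self.left_x) != n or len(self.right_x) != n:
            raise ValueError("channel length must equal round(fs * duration)")

    @property
    def n_samples(self) -> int:
        return len(self.left_x)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def generate_schedule(n_trials: int = 20, amplitude_deg: float = 16.0,
                      dwell_bounds: tuple = (1.3, 2.0), fs: float = 240.0,
                      seed: int = 0, duration: float | None = None) -> TargetSchedule:
    """Draw a pseudorandom task schedule.

    Left/right trial counts are balanced to within one; dwell durations are
    i.i.d. uniform on ``dwell_bounds``.  If ``duration`` is given and the
    full schedule does not fit inside it, an error naming the required
    duration is raised; otherwise the schedule may extend past any eventual
    recording window (the recording is then a crop of the task, as happens
    when a fixed-length video captures a longer task).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    lo, hi = dwell_bounds
    if not (0 < lo <= hi):
        raise ValueError("dwell_bounds must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    n_left = n_trials // 2
    dirs = np.array(["left"] * n_left + ["right"] * (n_trials - n_left))
    rng.shuffle(dirs)
    n_jumps = 2 * n_trials
    # one leading center dwell before the first jump + a dwell after each jump
    dwells = rng.uniform(lo, hi, size=n_jumps + 1)
    onsets = dwells[0] + np.concatenate(([0.0], np.cumsum(dwells[1:-1])))
    schedule_end = onsets[-1] + dwells[-1]
    if duration is not None and schedule_end > duration:
        raise ValueError(
            f"schedule requires {schedule_end:.2f} s but recording duration "
            f"is {duration:.2f} s")
    return TargetSchedule(tuple(dirs.tolist()), onsets, dwells[1:],
                          float(amplitude_deg))


def _transition(n: int) -> np.ndarray:
    """Unit transition 0 -> 1 over n samples: a logistic sigmoid rescaled to
    hit 0 and 1 exactly at its endpoints (compact support)."""
    u = np.linspace(0.0, 1.0, n)
    k = 10.0
    s = 1.0 / (1.0 + np.exp(-k * (u - 0.5)))
    s0 = 1.0 / (1.0 + np.exp(k * 0.5))
    return (s - s0) / (1.0 - 2.0 * s0)


def _add_step(x: np.ndarray, fs: float, t0: float, amplitude: float,
              duration_s: float) -> None:
    """Add a smooth step of given amplitude starting at t0 (in place)."""
    n = len(x)
    i0 = int(round(t0 * fs))
    if i0 >= n:
        return
    ntrans = max(int(round(duration_s * fs)), 2)
    i1 = min(i0 + ntrans, n)
    x[i0:i1] += amplitude * _transition(ntrans)[: i1 - i0]
    if i1 < n:
        x[i1:] += amplitude


def _saccade_duration(amplitude_nic: float) -> float:
    deg = abs(amplitude_nic) / DEG_TO_NIC
    return MS_SLOPE_S_PER_DEG * deg + MS_INTERCEPT_S


def _draw_gain(profile: SubjectProfile, rng: np.random.Generator) -> float:
    if profile.dysmetria_mode == "mixed":
        mean = profile.mixed_gain_means[rng.integers(2)]
    else:
        mean = profile.primary_gain_mean
    return mean + profile.primary_gain_sd * rng.standard_normal()


def simulate_recording(schedule: TargetSchedule, profile: SubjectProfile,
                       fs: float = 240.0, duration: float = 42.0,
                       seed: int = 0,
                       reaction_latency: float = 0.2) -> GazeRecording:
    """Render one binocular recording of the task.

    Only target jumps whose response falls inside the recording window are
    rendered; a schedule longer than the recording is cropped, mirroring a
    fixed-length video capture of a longer task.
    """
    if fs <= 0 or duration <= 0:
        raise ValueError("fs and duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    left = np.zeros(n)
    right = np.zeros(n)

    targets = schedule.target_positions()
    eye_l = 0.0
    eye_r = 0.0
    correct_thresh = 0.10 * schedule.amplitude_deg * DEG_TO_NIC
    n_saccades = 0
    for onset, target in zip(schedule.onset_times, targets):
        t_sacc = onset + reaction_latency + 0.02 * rng.standard_normal()
        if t_sacc >= duration:
            break
        gain = _draw_gain(profile, rng)
        asym = profile.left_right_asymmetry
        gain_r = gain * (1.0 + asym * rng.standard_normal())
        # disconjugate onset: the right eye launches slightly early/late
        t_sacc_r = t_sacc + 0.5 * asym * rng.standard_normal()
        step_l = gain * (target - eye_l)
        step_r = gain_r * (target - eye_r)
        dur = _saccade_duration(step_l)
        _add_step(left, fs, t_sacc, step_l, dur)
        _add_step(right, fs, t_sacc_r, step_r, _saccade_duration(step_r))
        eye_l += step_l
        eye_r += step_r
        n_saccades += 1
        # corrective saccades toward the target while the eye misses it:
        # dysmetric eyes settle through several steps, each after its own
        # latency
        t_prev_end = t_sacc + dur
        for _ in range(3):
            err_l = target - eye_l
            if abs(err_l) <= correct_thresh:
                break
            lat = max(profile.corrective_latency_mean
                      * (1.0 + 0.3 * rng.standard_normal()), 0.05)
            t_corr = t_prev_end + lat
            cg = profile.corrective_gain * (1.0 + 0.1 * rng.standard_normal())
            corr_l = cg * err_l
            corr_r = cg * (target - eye_r)
            t_corr_r = t_corr + 0.5 * asym * rng.standard_normal()
            if t_corr >= duration:
                break
            dur_c = _saccade_duration(corr_l)
            _add_step(left, fs, t_corr, corr_l, dur_c)
            _add_step(right, fs, t_corr_r, corr_r, _saccade_duration(corr_r))
            eye_l += corr_l
            eye_r += corr_r
            t_prev_end = t_corr + dur_c

    # blinks: Poisson events shared across both eyes, raised-cosine bumps
    # that return exactly to the pre-blink level
    blink_times = []
    if profile.blink_rate > 0:
        n_blinks = rng.poisson(profile.blink_rate * duration / 60.0)
        amp_nic = schedule.amplitude_deg * DEG_TO_NIC
        for _ in range(n_blinks):
            tb = rng.uniform(0.5, duration - 0.8)
            dur_b = rng.uniform(0.15, 0.25)
            i0 = int(round(tb * fs))
            nb = int(round(dur_b * fs))
            i1 = min(i0 + nb, n)
            bump = -1.25 * amp_nic * np.sin(np.pi * np.linspace(0, 1, nb)) ** 2
            left[i0:i1] += bump[: i1 - i0]
            right[i0:i1] += bump[: i1 - i0]
            blink_times.append(tb)

    if profile.drift_amplitude > 0:
        f_d = rng.uniform(0.02, 0.06)
        phase = rng.uniform(0, 2 * np.pi)
        drift = profile.drift_amplitude * np.sin(2 * np.pi * f_d * t + phase)
        left += drift
        right += drift

    if profile.noise_sd > 0:
        left += profile.noise_sd * rng.standard_normal(n)
        right += profile.noise_sd * rng.standard_normal(n)

    return GazeRecording(fs=fs, duration=duration, left_x=left, right_x=right,
                         label=profile.group_label, schedule=schedule,
                         meta={"profile": profile.to_dict(),
                               "blink_times": blink_times,
                               "n_primary_saccades": n_saccades,
                               "seed": int(seed)})


# -- cohort generation -------------------------------------------------------

#: per-group profile distributions: (low, high) uniform ranges.  Dysmetric
#: ranges span mild to severe disease, so subject traits vary much more
#: across the cohort than any one subject varies between sessions.
DEFAULT_COHORT_CONFIG = {
    "control": {
        "primary_gain_mean": (0.90, 0.98),
        "primary_gain_sd": (0.01, 0.03),
        "left_right_asymmetry": (0.005, 0.02),
        "corrective_latency_mean": (0.12, 0.18),
    },
    "hypometric": {
        "primary_gain_mean": (0.50, 0.84),
        "primary_gain_sd": (0.03, 0.10),
        "left_right_asymmetry": (0.02, 0.10),
        "corrective_latency_mean": (0.15, 0.40),
    },
    "hypermetric": {
        "primary_gain_mean": (1.12, 1.50),
        "primary_gain_sd": (0.03, 0.10),
        "left_right_asymmetry": (0.02, 0.10),
        "corrective_latency_mean": (0.15, 0.40),
    },
    "shared": {
        "blink_rate": (8.0, 18.0),
        "drift_amplitude": (0.01, 0.03),
        "noise_sd": (0.006, 0.014),
    },
}


def _draw_profile(mode: str, cfg: dict, rng: np.random.Generator) -> SubjectProfile:
    shared = {k: rng.uniform(*v) for k, v in cfg["shared"].items()}
    if mode == "none":
        g = cfg["control"]
        return SubjectProfile(
            group_label="control", dysmetria_mode="none",
            primary_gain_mean=rng.uniform(*g["primary_gain_mean"]),
            primary_gain_sd=rng.uniform(*g["primary_gain_sd"]),
            left_right_asymmetry=rng.uniform(*g["left_right_asymmetry"]),
            corrective_latency_mean=rng.uniform(*g["corrective_latency_mean"]),
            **shared)
    if mode == "mixed":
        g = cfg["hypometric"]
        hypo = rng.uniform(*g["primary_gain_mean"])
        hyper = rng.uniform(*cfg["hypermetric"]["primary_gain_mean"])
        return SubjectProfile(
            group_label="dysmetric", dysmetria_mode="mixed",
            primary_gain_mean=(hypo + hyper) / 2,
            mixed_gain_means=(hypo, hyper),
            primary_gain_sd=rng.uniform(*g["primary_gain_sd"]),
            left_right_asymmetry=rng.uniform(*g["left_right_asymmetry"]),
            corrective_latency_mean=rng.uniform(*g["corrective_latency_mean"]),
            **shared)
    g = cfg[mode]
    return SubjectProfile(
        group_label="dysmetric", dysmetria_mode=mode,
        primary_gain_mean=rng.uniform(*g["primary_gain_mean"]),
        primary_gain_sd=rng.uniform(*g["primary_gain_sd"]),
        left_right_asymmetry=rng.uniform(*g["left_right_asymmetry"]),
        corrective_latency_mean=rng.uniform(*g["corrective_latency_mean"]),
        **shared)


def generate_cohort(n_dysmetric: int, n_control: int,
                    config: dict | None = None, seed: int = 0,
                    fs: float = 240.0, duration: float = 42.0,
                    n_trials: int = 20) -> list[GazeRecording]:
    """Generate a labeled cohort; dysmetric subjects cycle through
    hypometric / hypermetric / mixed modes."""
    if n_dysmetric < 0 or n_control < 0:
        raise ValueError("cohort sizes must be non-negative")
    cfg = config or DEFAULT_COHORT_CONFIG
    root = np.random.default_rng(seed)
    modes = ["hypometric", "hypermetric", "mixed"]
    recordings = []
    specs = [modes[i % 3] for i in range(n_dysmetric)] + ["none"] * n_control
    for i, mode in enumerate(specs):
        sub_seed = int(root.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        profile = _draw_profile(mode, cfg, rng)
        sched = generate_schedule(n_trials=n_trials, fs=fs,
                                  seed=int(rng.integers(0, 2**31 - 1)))
        rec = simulate_recording(sched, profile, fs=fs, duration=duration,
                                 seed=int(rng.integers(0, 2**31 - 1)))
        rec.meta["subject_id"] = f"s{i:03d}"
        recordings.append(rec)
    return recordings


# -- I/O ---------------------------------------------------------------------

def write_recording(rec: GazeRecording, path: str | Path) -> None:
    """Write a recording to CSV (time,left_x,right_x) + sidecar JSON."""
    path = Path(path)
    df = pd.DataFrame({"time": rec.time, "left_x": rec.left_x,
                       "right_x": rec.right_x})
    df.to_csv(path, index=False, float_format="%.10g")
    side = {"fs": rec.fs, "duration": rec.duration, "label": rec.label,
            "meta": {k: v for k, v in rec.meta.items()},
            "schedule": rec.schedule.to_dict() if rec.schedule else None}
    path.with_suffix(".json").write_text(json.dumps(side, indent=1))


def read_recording(path: str | Path) -> GazeRecording:
    path = Path(path)
    df = pd.read_csv(path)
    side_path = path.with_suffix(".json")
    label = None
    fs = None
    meta = {}
    if side_path.exists():
        side = json.loads(side_path.read_text())
        label = side.get("label")
        fs = side.get("fs")
        meta = side.get("meta", {})
    if fs is None:
        dt = np.median(np.diff(df["time"].to_numpy()))
        fs = 1.0 / dt
    n = len(df)
    return GazeRecording(fs=fs, duration=n / fs,
                         left_x=df["left_x"].to_numpy(),
                         right_x=df["right_x"].to_numpy(),
                         label=label, meta=meta)
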