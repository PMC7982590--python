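"""Synthetic sagittal-plane gait trials.

Generates smooth, exactly periodic hip/knee/ankle angle trajectories over
one gait cycle from fixed truncated-Fourier templates, together with an
exogenous frontal-plane knee abduction moment profile. Stands in for motion
data packaged with commercial musculoskeletal software; user-supplied trials
can also be read from a plain CSV dialect (see :func:`read_trial_csv`).

Conventions: knee flexion, hip flexion and ankle dorsiflexion are positive;
the cycle starts at initial contact of the instrumented (right) foot and
stance occupies ``[0, stance_fraction)`` of the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import config

__all__ = [
    "SpeedPreset",
    "GaitTrial",
    "generate_gait",
    "differentiate",
    "read_trial_csv",
    "write_trial_csv",
]

_PERIODIC_ATOL = 1e-9

CSV_HEADER = [
    "time_s",
    "hip_flex_rad",
    "knee_flex_rad",
    "ankle_dorsi_rad",
    "knee_abd_moment_Nm",
]


@dataclass(frozen=True)
class SpeedPreset:
    """Walking-speed condition: mean speed, cycle duration and stance share.

    ``amplitude_scale`` scales each angle template's deviation from its cycle
    mean; the fast preset uses a mildly larger value together with a shorter
    cycle.
    """

    name: str
    mean_speed: float       # m/s
    cycle_duration: float   # s
    stance_fraction: float  # (0, 1)
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.mean_speed > 0:
            raise ValueError("SpeedPreset.mean_speed must be > 0")
        if not self.cycle_duration > 0:
            raise ValueError("SpeedPreset.cycle_duration must be > 0")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("SpeedPreset.stance_fraction must be in (0, 1)")

    @classmethod
    def from_name(cls, name: str) -> "SpeedPreset":
        try:
            speed, duration, stance, amp = config.SPEED_PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown speed preset {name!r}; expected one of "
                f"{sorted(config.SPEED_PRESETS)}"
            ) from None
        return cls(name, speed, duration, stance, amp)


@dataclass
class GaitTrial:
    """One gait cycle of sagittal joint kinematics plus the frontal-plane
    knee abduction moment.

    All angle channels are exactly periodic (first == last sample) and the
    time vector spans exactly one ``cycle_duration``. ``events`` is the
    stance interval of the instrumented leg as fractions of the cycle.
    """

    time: np.ndarray
    hip_flexion: np.ndarray
    knee_flexion: np.ndarray
    ankle_dorsiflexion: np.ndarray
    knee_abduction_moment: np.ndarray
    events: tuple[float, float]
    speed_preset: SpeedPreset

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for ch in ("hip_flexion", "knee_flexion", "ankle_dorsiflexion",
                   "knee_abduction_moment"):
            setattr(self, ch, np.asarray(getattr(self, ch), dtype=float))
        n = self.time.size
        if n < 2:
            raise ValueError("GaitTrial needs at least 2 frames")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("GaitTrial.time must be strictly increasing")
        span = self.time[-1] - self.time[0]
        if abs(span - self.speed_preset.cycle_duration) > 1e-9:
            raise ValueError(
                "GaitTrial.time must span exactly one cycle_duration "
                f"(got {span}, expected {self.speed_preset.cycle_duration})"
            )
        for ch in ("hip_flexion", "knee_flexion", "ankle_dorsiflexion",
                   "knee_abduction_moment"):
            arr = getattr(self, ch)
            if arr.shape != self.time.shape:
                raise ValueError(f"channel {ch} length mismatch")
            if abs(arr[0] - arr[-1]) >= _PERIODIC_ATOL:
                raise ValueError(f"channel {ch} is not periodic")
        if np.any(self.knee_flexion < -1e-12):
            raise ValueError("knee_flexion must be >= 0 (flexion-positive)")
        lo, hi = self.events
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("events must be an interval within [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.time.size

    @property
    def phase(self) -> np.ndarray:
        """Gait-cycle fraction of each frame, in [0, 1]."""
        return (self.time - self.time[0]) / self.speed_preset.cycle_duration

    def in_stance(self) -> np.ndarray:
        """Boolean stance mask for the instrumented leg (phase 1 wraps to 0)."""
        lo, hi = self.events
        ph = np.mod(self.phase, 1.0)
        return (ph >= lo) & (ph < hi)

    def channels(self) -> dict[str, np.ndarray]:
        return {
            "hip_flexion": self.hip_flexion,
            "knee_flexion": self.knee_flexion,
            "ankle_dorsiflexion": self.ankle_dorsiflexion,
            "knee_abduction_moment": self.knee_abduction_moment,
        }


def _eval_template(tpl: dict, phase: np.ndarray, amplitude_scale: float) -> np.ndarray:
    a0 = tpl["a0"]
    out = np.zeros_like(phase)
    for k, (ak, bk) in enumerate(zip(tpl["ak"], tpl["bk"]), start=1):
        out += ak * np.cos(2 * np.pi * k * phase) + bk * np.sin(2 * np.pi * k * phase)
    return a0 + amplitude_scale * out


def _mkad_template(phase: np.ndarray, stance_fraction: float,
                   peak: float, dip: float) -> np.ndarray:
    """Positive double-hump adduction-loading moment over stance, zero in swing.

    Shape: ``s (1 - dip * s)`` with ``s = sin^2(pi x)`` on the normalized
    stance coordinate x; value and slope vanish at both stance boundaries.
    """
    x = np.mod(phase, 1.0) / stance_fraction
    s = np.sin(np.pi * np.clip(x, 0.0, 1.0)) ** 2
    raw = s * (1.0 - dip * s)
    raw[x >= 1.0] = 0.0
    s_star = min(1.0, 1.0 / (2.0 * dip)) if dip > 0 else 1.0
    peak_raw = s_star * (1.0 - dip * s_star)
    return peak * raw / peak_raw


def generate_gait(
    preset: SpeedPreset,
    n_frames: int = 101,
    seed: int = 0,
    noise: float = 0.0,
    mkad_peak: float = config.MKAD_PEAK_NM,
) -> GaitTrial:
    """Generate one synthetic gait cycle.

    Deterministic for fixed ``(preset, n_frames, seed)``: the angle channels
    are evaluated from the fixed Fourier templates at the frame phases, so
    doubling ``n_frames`` leaves values at shared phases unchanged. ``seed``
    only feeds the optional small Fourier perturbation controlled by
    ``noise`` (default 0, i.e. no randomness).

    Parameters
    ----------
    preset : SpeedPreset
        Walking condition (speed, cycle duration, stance fraction).
    n_frames : int
        Samples spanning the cycle including both (identical) endpoints.
        At least 21 so finite differencing downstream is meaningful.
    seed : int
        Seed for the optional noise perturbation.
    noise : float
        Standard deviation (radians) of a smooth random perturbation added
        to each angle channel; 0 disables it.
    mkad_peak : float
        Peak knee abduction moment in N*m.
    """
    if n_frames < 21:
        raise ValueError(
            f"n_frames={n_frames} too small for finite differencing; need >= 21"
        )
    phase = np.linspace(0.0, 1.0, n_frames)
    time = phase * preset.cycle_duration

    channels = {}
    rng = np.random.default_rng(seed)
    for name in ("hip_flexion", "knee_flexion", "ankle_dorsiflexion"):
        tpl = config.FOURIER_TEMPLATES[name]
        arr = _eval_template(tpl, phase, preset.amplitude_scale)
        if noise > 0.0:
            # smooth periodic perturbation: 2 low harmonics, zero-mean
            amp = rng.normal(0.0, noise, size=2)
            ph0 = rng.uniform(0.0, 2 * np.pi, size=2)
            for k in (1, 2):
                arr = arr + amp[k - 1] * np.sin(2 * np.pi * k * phase + ph0[k - 1])
        channels[name] = arr
    channels["knee_flexion"] = np.maximum(channels["knee_flexion"], 0.0)

    mkad = _mkad_template(phase, preset.stance_fraction, mkad_peak, config.MKAD_DIP)

    return GaitTrial(
        time=time,
        hip_flexion=channels["hip_flexion"],
        knee_flexion=channels["knee_flexion"],
        ankle_dorsiflexion=channels["ankle_dorsiflexion"],
        knee_abduction_moment=mkad,
        events=(0.0, preset.stance_fraction),
        speed_preset=preset,
    )


def differentiate(series: np.ndarray, time: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivatives of a cyclic, uniformly sampled series.

    Central differences on the interior with periodic wrap at the ends; the
    second derivative is the first-derivative stencil applied twice, so both
    converge at O(dt^2). The series must carry the duplicated cycle endpoint
    (``series[0] == series[-1]``).

    Raises
    ------
    ValueError
        If fewer than 5 frames, non-uniform spacing (tolerance 1e-9 s), or a
        non-periodic series is passed.
    """
    series = np.asarray(series, dtype=float)
    time = np.asarray(time, dtype=float)
    n = series.size
    if n < 5:
        raise ValueError("differentiate needs at least 5 frames")
    if time.shape != series.shape:
        raise ValueError("series and time must have the same length")
    dts = np.diff(time)
    dt = dts[0]
    if np.any(np.abs(dts - dt) > 1e-9):
        raise ValueError("differentiate requires uniform time spacing")
    scale = max(np.ptp(series), 1.0)
    if abs(series[0] - series[-1]) > 1e-9 * scale:
        raise ValueError("series is not periodic (first != last sample)")

    def _cyc_diff(u: np.ndarray) -> np.ndarray:
        # u has n-1 unique samples; duplicated endpoint handled by caller
        core = u[:-1]
        d = (np.roll(core, -1) - np.roll(core, 1)) / (2.0 * dt)
        return np.append(d, d[0])

    d1 = _cyc_diff(series)
    d2 = _cyc_diff(d1)
    return d1, d2


def phase_shift(series: np.ndarray, shift: float) -> np.ndarray:
    """Shift a cyclic series (duplicated endpoint) by a cycle fraction.

    Exact (a roll) when the shift is an integer number of steps, periodic
    linear interpolation otherwise.
    """
    series = np.asarray(series, dtype=float)
    n = series.size - 1
    steps = shift * n
    k = int(round(steps))
    if abs(steps - k) < 1e-9:
        core = np.roll(series[:-1], -k)
    else:
        idx = (np.arange(n) + steps) % n
        lo = np.floor(idx).astype(int)
        w = idx - lo
        core = (1 - w) * series[:-1][lo % n] + w * series[:-1][(lo + 1) % n]
    return np.append(core, core[0])


def write_trial_csv(trial: GaitTrial, path) -> None:
    """Write a trial in the plain CSV time-series dialect."""
    df = pd.DataFrame(
        {
            "time_s": trial.time,
            "hip_flex_rad": trial.hip_flexion,
            "knee_flex_rad": trial.knee_flexion,
            "ankle_dorsi_rad": trial.ankle_dorsiflexion,
            "knee_abd_moment_Nm": trial.knee_abduction_moment,
        }
    )
    df.to_csv(path, index=False)


def read_trial_csv(path, speed_preset: SpeedPreset | None = None) -> GaitTrial:
    """Read a trial from the CSV dialect (also the user-supplied format).

    If no preset is given, a preset is built from the file's time span with
    the default stance fraction and the normal-walk mean speed.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV missing columns: {missing}")
    time = df["time_s"].to_numpy(dtype=float)
    if speed_preset is None:
        speed, _, stance, amp = config.SPEED_PRESETS["normal"]
        speed_preset = SpeedPreset(
            "custom", speed, float(time[-1] - time[0]), stance, amp
        )
    return GaitTrial(
        time=time,
        hip_flexion=df["hip_flex_rad"].to_numpy(dtype=float),
        knee_flexion=df["knee_flex_rad"].to_numpy(dtype=float),
        ankle_dorsiflexion=df["ankle_dorsi_rad"].to_numpy(dtype=float),
        knee_abduction_moment=df["knee_abd_moment_Nm"].to_numpy(dtype=float),
        events=(0.0, speed_preset.stance_fraction),
        speed_preset=speed_preset,
    )
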