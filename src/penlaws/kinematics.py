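"""Copy-game kinematic preprocessing.

The per-execution speed statistic follows the study pipeline: drop the first
and last 5% of the samples (pen landing/lift transients), differentiate the
pen-down trace, low-pass the speed signal at 10 Hz (zero-phase, 4th-order
Butterworth), and average to a single mm/s value per execution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import NonUniformSamplingError, TooShortError, ValidationError
from .io import TrialRecording

#: Minimum number of speed samples for a stable zero-phase filter start-up.
MIN_FILTER_SAMPLES = 16


@dataclass
class SpeedProfile:
    """Instantaneous speed at sample-pair midpoints.

    ``t_mid[i]`` is the midpoint of the pair (i, i+1); pairs spanning a
    pen-up gap are excluded, so ``t_mid`` may contain jumps at pen lifts.
    """

    t_mid: np.ndarray
    v: np.ndarray
    filtered: bool = False

    def __post_init__(self) -> None:
        self.t_mid = np.asarray(self.t_mid, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if len(self.t_mid) != len(self.v):
            raise ValueError("t_mid and v must have equal length")


def trim_borders(trial: TrialRecording, fraction: float = 0.05) -> TrialRecording:
    """Drop the first and last ``floor(fraction * N)`` samples of a trial."""
    if not 0 <= fraction < 0.5:
        raise ValueError(f"fraction must be in [0, 0.5), got {fraction}")
    n = len(trial)
    if n < 3:
        raise TooShortError(f"need >=3 samples to trim, got {n}")
    k = int(np.floor(fraction * n))
    if n - 2 * k < 2:
        raise TooShortError(f"trimming {k} samples each end leaves <2 of {n}")
    sl = slice(k, n - k) if k else slice(None)
    return replace(
        trial, t=trial.t[sl], x=trial.x[sl], y=trial.y[sl],
        pen_down=trial.pen_down[sl],
        pressure=None if trial.pressure is None else trial.pressure[sl])


def path_length(trial: TrialRecording) -> float:
    """Traced ink length in mm: Euclidean sum over pen-down segments.

    A segment contributes only when both endpoints are pen-down, so pen-up
    gaps add nothing.
    """
    if len(trial) < 2:
        raise TooShortError("need >=2 samples for a path length")
    dx = np.diff(trial.x)
    dy = np.diff(trial.y)
    down_pair = trial.pen_down[:-1] & trial.pen_down[1:]
    return float(np.sum(np.hypot(dx, dy)[down_pair]))


def raw_speed(trial: TrialRecording) -> SpeedProfile:
    """Discrete-difference speed over pen-down sample pairs."""
    if len(trial) < 2:
        raise TooShortError("need >=2 samples for a speed profile")
    dt = np.diff(trial.t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise ValidationError(f"non-increasing timestamps at sample index {bad[0]}")
    down_pair = trial.pen_down[:-1] & trial.pen_down[1:]
    dist = np.hypot(np.diff(trial.x), np.diff(trial.y))
    v = dist[down_pair] / dt[down_pair]
    t_mid = (trial.t[:-1] + trial.t[1:])[down_pair] / 2.0
    return SpeedProfile(t_mid=t_mid, v=v, filtered=False)


def lowpass(profile: SpeedProfile, cutoff_hz: float = 10.0,
            order: int = 4) -> SpeedProfile:
    """Zero-phase Butterworth low-pass of the speed signal.

    The speed series is treated as uniformly sampled at the median rate
    (pen-lift gaps are bridged); negative filter outputs are clamped to 0.
    Raises :class:`TooShortError` on short profiles — callers fall back to
    the raw profile — and :class:`NonUniformSamplingError` when the
    within-stroke sampling deviates more than 20% from the median interval.
    """
    n = len(profile.v)
    if n < MIN_FILTER_SAMPLES:
        raise TooShortError(
            f"{n} speed samples < {MIN_FILTER_SAMPLES}; skip filtering and use the raw profile")
    dt = np.diff(profile.t_mid)
    med = float(np.median(dt))
    if med <= 0:
        raise NonUniformSamplingError("non-positive median sampling interval")
    within = dt[dt <= 1.5 * med]  # larger gaps are pen lifts, bridged below
    if np.any(np.abs(within / med - 1.0) > 0.2):
        raise NonUniformSamplingError(
            "sampling deviates >20% from the median interval; filtering assumes ~uniform rate")
    fs = 1.0 / med
    if fs <= 2.0 * cutoff_hz:
        raise NonUniformSamplingError(
            f"sampling rate {fs:.1f} Hz too low for a {cutoff_hz:g} Hz cutoff")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    v = signal.sosfiltfilt(sos, profile.v)
    return SpeedProfile(t_mid=profile.t_mid.copy(), v=np.maximum(v, 0.0),
                        filtered=True)


def mean_speed(trial: TrialRecording, trim_fraction: float = 0.05,
               cutoff_hz: float = 10.0, order: int = 4) -> float:
    """Single mm/s value per execution: trim -> differentiate -> 10 Hz -> mean.

    Trials too short to filter fall back to the raw speed profile.
    """
    trimmed = trim_borders(trial, trim_fraction)
    profile = raw_speed(trimmed)
    if profile.v.size == 0:
        raise TooShortError("no pen-down sample pairs after trimming")
    try:
        profile = lowpass(profile, cutoff_hz=cutoff_hz, order=order)
    except TooShortError:
        pass
    return float(np.mean(profile.v))
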