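"""Muscle activity from EMG: windowed-envelope recursion with MVC normalization.

The activity drive a_k follows a first-order tracking recursion toward the
rectified EMG summed over a short trailing window,

    a_k = a_{k-1} + dt * (S_k - a_{k-1}) / D,      S_k = sum_{j=k-n}^{k-1} |e_j|,

with an asymmetric time constant: D = d_rise (0.04 s) while the windowed sum
exceeds the current level (activation builds quickly) and D = d_fall (0.07 s)
otherwise (decay is slower).  Normalized activity is A_k = a_k / a_MVC, the
fraction of the maximal-voluntary-contraction level.

For constant rectified input |e| = c the recursion has fixed point a* = n*c,
which anchors the calibration: a_MVC is the peak of the same recursion run on
an MVC trial.

Note on provenance of the formula: the published recursion prints the summand
as |e_k| under a sum over j, and compares an undefined quantity "i_k" against
a_{k-1} to pick D.  Both are read here in the only self-consistent way: the
sum runs over the window samples |e_j|, and the switch compares that windowed
sum to a_{k-1}.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EMGSeries:
    """A single-channel EMG recording with the recursion's parameters.

    samples : raw EMG values e_k (any units; only |e| enters).
    dt : sample timestep in seconds.
    n_window : trailing window length n (samples), default 3.
    d_rise / d_fall : asymmetric time constants in seconds (0.04 / 0.07).
    a_mvc : activity level of maximal voluntary contraction (> 0).
    """

    samples: np.ndarray
    dt: float
    a_mvc: float = 1.0
    n_window: int = 3
    d_rise: float = 0.04
    d_fall: float = 0.07

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_window < 1:
            raise ValueError("n_window must be >= 1")
        if self.dt / self.d_rise >= 2:
            raise ValueError("dt/d_rise >= 2: recursion unstable")


@dataclass
class ActivitySeries:
    """Per-frame normalized muscle activity, one column per muscle."""

    values: np.ndarray  # (n_frames,) or (n_frames, n_muscles)
    times: np.ndarray  # seconds

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64).ravel()
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("values and times must have the same length")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def _activity_drive(series: EMGSeries, a0: float) -> np.ndarray:
    e = np.abs(series.samples)
    n = series.n_window
    a = np.empty(len(e))
    prev = float(a0)
    # trailing window sum over j = k-n .. k-1, zero-padded at the start
    csum = np.concatenate([[0.0], np.cumsum(e)])
    for k in range(len(e)):
        lo = max(k - n, 0)
        s = csum[k] - csum[lo]
        d = series.d_rise if s > prev else series.d_fall
        prev = prev + series.dt * (s - prev) / d
        a[k] = prev
    return a


def muscle_activity(series: EMGSeries, a0: float = 0.0) -> ActivitySeries:
    """Run the activity recursion and normalize by the MVC level (A_k = a_k/a_MVC)."""
    if series.a_mvc <= 0:
        raise ValueError("a_mvc must be positive")
    a = _activity_drive(series, a0)
    times = np.arange(len(a)) * series.dt
    return ActivitySeries(a / series.a_mvc, times)


def calibrate_mvc(mvc_series: EMGSeries, a0: float = 0.0) -> float:
    """MVC activity level: peak of the recursion run on an MVC recording."""
    return float(_activity_drive(mvc_series, a0).max())


def read_emg_csv(path, time_column: str = "time", emg_column: str = "emg",
                 **series_kwargs) -> EMGSeries:
    """Read a (time, emg) CSV into an :class:`EMGSeries` (dt from the time column)."""
    df = pd.read_csv(path)
    t = df[time_column].to_numpy(float)
    if len(t) < 2:
        raise ValueError("EMG series needs at least two samples")
    dt = float(np.median(np.diff(t)))
    return EMGSeries(df[emg_column].to_numpy(float), dt=dt, **series_kwargs)


def resample_to_frames(activity: ActivitySeries, frame_times: np.ndarray) -> ActivitySeries:
    """Align activity samples to mesh frame times by nearest timestamp."""
    frame_times = np.asarray(frame_times, float).ravel()
    idx = np.clip(np.searchsorted(activity.times, frame_times), 0, activity.n_frames - 1)
    left = np.clip(idx - 1, 0, activity.n_frames - 1)
    pick = np.where(
        np.abs(activity.times[left] - frame_times)
        <= np.abs(activity.times[idx] - frame_times),
        left, idx)
    return ActivitySeries(activity.values[pick], frame_times)
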