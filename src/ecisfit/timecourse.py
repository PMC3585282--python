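"""Single-frequency impedance timecourses (monolayer monitoring at 4000 Hz).

ECIS experiments record the complex impedance at one frequency (typically
4000 Hz) over hours to verify monolayer stability and capture the response
to a stimulus.  These utilities compute the standard macroscopic readouts
(|Z|, series-RC decomposition) and summarise pre/post-stimulus windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidArgumentError
from .model import series_rc_equivalent

__all__ = ["TimecourseTrace", "magnitude_trace", "rc_trace", "pre_post_summary"]


@dataclass
class TimecourseTrace:
    """Complex impedance at a fixed frequency over time, whole-electrode Ω."""

    electrode_id: str
    times_s: np.ndarray
    z_real_ohm: np.ndarray
    z_imag_ohm: np.ndarray
    frequency_hz: float = 4000.0
    stimulus_time_s: float | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.z_real_ohm = np.asarray(self.z_real_ohm, dtype=float)
        self.z_imag_ohm = np.asarray(self.z_imag_ohm, dtype=float)
        if not (self.frequency_hz > 0):
            raise InvalidArgumentError("frequency must be positive")
        n = len(self.times_s)
        if len(self.z_real_ohm) != n or len(self.z_imag_ohm) != n:
            raise InvalidArgumentError("time and impedance sequences must be aligned")
        if n and not np.all(np.diff(self.times_s) > 0):
            raise InvalidArgumentError("times must be strictly increasing")

    @property
    def z_ohm(self) -> np.ndarray:
        return self.z_real_ohm + 1j * self.z_imag_ohm

    def subset(self, mask: np.ndarray) -> "TimecourseTrace":
        return TimecourseTrace(self.electrode_id, self.times_s[mask],
                               self.z_real_ohm[mask], self.z_imag_ohm[mask],
                               self.frequency_hz, self.stimulus_time_s)


def magnitude_trace(trace: TimecourseTrace) -> np.ndarray:
    """(time_s, |Z| Ω) pairs — the absolute-value plot of a timecourse."""
    return np.column_stack([trace.times_s, np.abs(trace.z_ohm)])


def rc_trace(trace: TimecourseTrace) -> np.ndarray:
    """(time_s, r_series Ω, c_series F): pointwise series-RC interpretation."""
    rc = np.array([series_rc_equivalent(z, trace.frequency_hz) for z in trace.z_ohm])
    return np.column_stack([trace.times_s, rc])


def pre_post_summary(trace: TimecourseTrace,
                     pre_window_s: tuple | None = None,
                     post_window_s: tuple | None = None,
                     n_pre_samples: int = 30,
                     settling_lag_s: float = 600.0):
    """Mean |Z| before and after the stimulus, and their post/pre ratio.

    Default windows: the ``n_pre_samples`` samples ending at the stimulus,
    and everything from ``settling_lag_s`` after the stimulus to the end of
    the trace (stimulus responses need time to settle before a plateau
    mean is meaningful).  Explicit ``(t0, t1)`` windows override either
    default; they must not overlap.  Gaps in sampling are tolerated —
    windows use whatever samples they contain.
    """
    if trace.stimulus_time_s is None:
        raise InvalidArgumentError("trace has no stimulus annotation")
    t = trace.times_s
    mag = np.abs(trace.z_ohm)
    t_stim = trace.stimulus_time_s

    if pre_window_s is None:
        pre_idx = np.flatnonzero(t <= t_stim)[-n_pre_samples:]
        pre_mask = np.zeros_like(t, dtype=bool)
        pre_mask[pre_idx] = True
    else:
        pre_mask = (t >= pre_window_s[0]) & (t <= pre_window_s[1])
    if post_window_s is None:
        post_mask = t >= t_stim + settling_lag_s
    else:
        post_mask = (t >= post_window_s[0]) & (t <= post_window_s[1])

    if np.any(pre_mask & post_mask):
        raise InvalidArgumentError("pre and post windows overlap")
    if not pre_mask.any():
        raise InsufficientDataError("pre-stimulus window contains no samples")
    if not post_mask.any():
        raise InsufficientDataError("post-stimulus window contains no samples")

    pre_mean = float(mag[pre_mask].mean())
    post_mean = float(mag[post_mask].mean())
    return pre_mean, post_mean, post_mean / pre_mean
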