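"""Segmentation of eye-position traces into saccades and fixations.

Larval zebrafish in the dark alternate rapid horizontal eye movements
(saccades) with multi-second epochs of stable eye position (fixations).
This module detects saccades from a velocity threshold applied to a
median-filtered eye-position trace, tiles the inter-saccade intervals
into fixations, and computes the behavioral summary statistics used by
the downstream neural analyses (fixation-duration quantiles,
same-direction transition fraction, amplitude medians, and the eye
position power spectrum).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

__all__ = [
    "EyeTrace",
    "SaccadeEvent",
    "FixationInterval",
    "median_filter_position",
    "detect_saccades",
    "segment_fixations",
    "behavior_summary",
    "position_power_spectrum",
]

#: minimum allowed spacing between accepted saccadic events (s); threshold
#: crossings closer than this to the previous accepted event are treated as
#: body-movement artifacts and discarded.
MIN_EVENT_GAP_S = 1.4

#: absolute floor on the saccade velocity threshold (deg/s)
VELOCITY_FLOOR_DEG_S = 10.0


@dataclass
class EyeTrace:
    """Horizontal eye position samples for one eye.

    Attributes
    ----------
    time_s : ndarray
        Nondecreasing sample times in seconds (~13 Hz for camera data).
    position_deg : ndarray
        Horizontal eye position in degrees; NaN marks masked samples.
    eye_label : str
        ``"left"`` or ``"right"``.
    """

    time_s: np.ndarray
    position_deg: np.ndarray
    eye_label: str = "left"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.position_deg = np.asarray(self.position_deg, dtype=float)
        if self.time_s.shape != self.position_deg.shape:
            raise ValueError("time_s and position_deg must have equal length")
        if self.time_s.size and np.any(np.diff(self.time_s) < 0):
            raise ValueError("time_s must be nondecreasing")

    @property
    def sample_rate_hz(self) -> float:
        dt = np.median(np.diff(self.time_s))
        if not np.isfinite(dt) or dt <= 0:
            raise ValueError("cannot infer sample rate from time_s")
        return 1.0 / dt


@dataclass(frozen=True)
class SaccadeEvent:
    """A detected rapid eye movement.

    ``onset_time_s`` is the time of the first supra-threshold velocity
    sample of the event run.  ``direction`` is ``"R"`` for positive
    (rightward) position change and ``"L"`` otherwise.
    """

    onset_time_s: float
    direction: str
    amplitude_deg: float
    peak_velocity_deg_s: float


@dataclass(frozen=True)
class FixationInterval:
    """Inter-saccade interval bounded by two detected saccades."""

    start_s: float
    end_s: float
    preceding_direction: str
    following_direction: str

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _median_filter_order(window_s: float, sample_rate_hz: float) -> int:
    order = int(round(window_s * sample_rate_hz))
    if order % 2 == 0:
        order += 1
    return max(order, 1)


def median_filter_position(trace: EyeTrace, window_s: float = 0.5) -> EyeTrace:
    """Median-filter the eye position to suppress tracking fluctuations.

    The filter order corresponds to ``window_s`` (default 500 ms) at the
    trace's native sampling rate, forced odd so the window is centered.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if trace.time_s.size == 0:
        raise ValueError("empty trace")
    order = _median_filter_order(window_s, trace.sample_rate_hz)
    filtered = _signal.medfilt(trace.position_deg, kernel_size=order)
    return EyeTrace(trace.time_s.copy(), filtered, trace.eye_label)


def detect_saccades(
    trace: EyeTrace,
    window_s: float = 0.5,
    min_gap_s: float = MIN_EVENT_GAP_S,
    velocity_floor_deg_s: float = VELOCITY_FLOOR_DEG_S,
) -> list[SaccadeEvent]:
    """Detect saccades as threshold crossings of eye velocity.

    Velocity is the first difference of the median-filtered position
    divided by the sample interval.  The threshold is the larger of
    ``mean(|v|) + 3*std(v)`` and ``velocity_floor_deg_s``.  A run of
    consecutive supra-threshold samples is a single event timed at its
    first sample; its amplitude is the filtered-position change across
    the run.  Events within ``min_gap_s`` of the previously accepted
    event are discarded (the later event of a close pair is dropped).
    """
    if trace.time_s.size < 2:
        raise ValueError("need at least two samples to compute velocity")
    if not np.isfinite(trace.position_deg).any():
        raise ValueError("velocity is all-NaN")
    filt = median_filter_position(trace, window_s=window_s)
    dt = np.diff(filt.time_s)
    dt[dt == 0] = np.nan
    velocity = np.diff(filt.position_deg) / dt
    finite = np.isfinite(velocity)
    if not finite.any():
        raise ValueError("velocity is all-NaN")
    threshold = max(
        np.nanmean(np.abs(velocity)) + 3.0 * np.nanstd(velocity),
        velocity_floor_deg_s,
    )
    above = np.zeros(velocity.size, dtype=bool)
    above[finite] = np.abs(velocity[finite]) > threshold

    events: list[SaccadeEvent] = []
    last_kept = -np.inf
    i = 0
    n = above.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        onset = filt.time_s[i]
        if onset - last_kept > min_gap_s:
            amp = filt.position_deg[j + 1] - filt.position_deg[i]
            run = velocity[i : j + 1]
            peak = run[np.nanargmax(np.abs(run))]
            direction = "R" if (amp if amp != 0 else peak) > 0 else "L"
            events.append(
                SaccadeEvent(
                    onset_time_s=float(onset),
                    direction=direction,
                    amplitude_deg=float(abs(amp)),
                    peak_velocity_deg_s=float(peak),
                )
            )
            last_kept = onset
        i = j + 1
    return events


def segment_fixations(
    events: list[SaccadeEvent], trace: EyeTrace | None = None
) -> list[FixationInterval]:
    """Tile the intervals between adjacent saccades into fixations.

    Returns one interval per adjacent event pair (``n - 1`` fixations for
    ``n`` events); fewer than two events yields an empty list.
    """
    if len(events) < 2:
        return []
    out = []
    for a, b in zip(events[:-1], events[1:]):
        if b.onset_time_s <= a.onset_time_s:
            raise ValueError("events must be strictly ordered in time")
        out.append(
            FixationInterval(
                start_s=a.onset_time_s,
                end_s=b.onset_time_s,
                preceding_direction=a.direction,
                following_direction=b.direction,
            )
        )
    return out


def same_direction_fraction(directions: list[str] | np.ndarray) -> float:
    """Fraction of saccades made in the same direction as the previous one."""
    d = np.asarray(directions)
    if d.size < 2:
        raise ValueError("need at least two saccades")
    return float(np.mean(d[1:] == d[:-1]))


def behavior_summary(
    events: list[SaccadeEvent],
    fixations: list[FixationInterval],
    trace: EyeTrace | None = None,
) -> dict:
    """Summary statistics of the saccade/fixation pattern.

    Returns the median and 1st/99th-percentile fixation durations, the
    same-direction transition fraction, amplitude medians split by
    whether the saccade repeated the previous direction, and (when
    ``trace`` is given) the 1st–99th percentile eye-position range.
    """
    if not events or not fixations:
        raise ValueError("need nonempty events and fixations")
    durations = np.array([f.duration_s for f in fixations])
    directions = np.array([e.direction for e in events])
    amplitudes = np.array([e.amplitude_deg for e in events])
    same = directions[1:] == directions[:-1]
    out = {
        "n_saccades": len(events),
        "n_fixations": len(fixations),
        "fixation_median_s": float(np.median(durations)),
        "fixation_p01_s": float(np.percentile(durations, 1)),
        "fixation_p99_s": float(np.percentile(durations, 99)),
        "same_direction_fraction": same_direction_fraction(directions),
        "amplitude_median_deg": float(np.median(amplitudes)),
        "amplitude_median_same_deg": (
            float(np.median(amplitudes[1:][same])) if same.any() else np.nan
        ),
        "amplitude_median_opposite_deg": (
            float(np.median(amplitudes[1:][~same])) if (~same).any() else np.nan
        ),
    }
    if trace is not None:
        pos = trace.position_deg[np.isfinite(trace.position_deg)]
        out["position_range_deg"] = float(
            np.percentile(pos, 99) - np.percentile(pos, 1)
        )
    return out


def position_power_spectrum(
    trace: EyeTrace,
    nperseg: int | None = None,
    power_fraction: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Welch power spectral density of eye position.

    The trace is linearly resampled to its median sampling interval
    before the PSD is computed.  Returns ``(freqs, psd, f_cut)`` where
    ``f_cut`` is the lowest frequency below which ``power_fraction`` of
    the non-DC power lies.
    """
    t, p = trace.time_s, trace.position_deg
    ok = np.isfinite(p)
    t, p = t[ok], p[ok]
    if t.size < 8:
        raise ValueError("trace too short for a PSD estimate")
    dt = float(np.median(np.diff(t)))
    grid = np.arange(t[0], t[-1], dt)
    resampled = np.interp(grid, t, p)
    if nperseg is None:
        nperseg = min(1024, resampled.size)
    if resampled.size < nperseg:
        raise ValueError("trace shorter than one Welch segment")
    freqs, psd = _signal.welch(resampled, fs=1.0 / dt, nperseg=nperseg)
    nondc = psd[1:]
    cumulative = np.cumsum(nondc) / np.sum(nondc)
    f_cut = float(freqs[1:][np.searchsorted(cumulative, power_fraction)])
    return freqs, psd, f_cut
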