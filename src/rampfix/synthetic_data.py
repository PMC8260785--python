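"""Synthetic eye-movement, calcium-trace, and imaging data with known ground truth.

The generators emulate the statistical structure of spontaneous saccadic
behavior in larval zebrafish and of the nuclear-localized calcium signals
recorded during it:

* alternating left/right saccades with a configurable probability
  (default 0.23) of repeating the previous direction;
* fixation durations drawn from a truncated log-normal with median
  11.4 s whose 1st/99th percentiles fall near 2/50 s;
* direction-dependent saccade amplitudes (median 8 deg when repeating the
  previous direction, 13 deg otherwise);
* cells of four archetypes — tonic, burst, burst-tonic, and pre-saccadic
  rise (SR) — whose deconvolved activity is convolved with an exponential
  calcium kernel (tau = 1.3 s) to produce fluorescence;
* SR cells obey ramp-to-threshold structure: within each fixation ending
  in the cell's preferred direction, activity ramps linearly from a random
  onset so that slope x rise-duration equals a common threshold kappa.

Every generator is deterministic given its configuration and seed, and the
ground truth of every event (saccade times, directions, per-fixation rise
onsets and slopes) is returned so downstream detectors and estimators can
be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .behavior import EyeTrace
from .sta_analysis import CellTrace
from .ablation_analysis import AblationExperiment

__all__ = [
    "BehaviorConfig",
    "SRCellConfig",
    "GroundTruth",
    "RiseTruth",
    "gen_eye_trace",
    "gen_sr_cell",
    "gen_archetype_cell",
    "gen_frames",
    "gen_intensity_image",
    "gen_ablation_experiments",
    "gen_sr_map",
]

#: log-normal shape parameter giving 1st/99th fixation-duration
#: percentiles near 2/50 s for a median of 11.4 s
FIXATION_SIGMA = 0.636

#: Beta parameters for the fraction of the fixation occupied by the
#: pre-saccadic rise; gives a broad distribution of normalized rise
#: times with median time-before-saccade near 5 s at the default
#: fixation statistics
RISE_FRACTION_BETA = (2.0, 2.5)


@dataclass
class BehaviorConfig:
    """Parameters of the simulated saccade/fixation behavior."""

    sample_rate_hz: float = 13.0
    p_same_direction: float = 0.23
    fixation_median_s: float = 11.4
    fixation_sigma: float = FIXATION_SIGMA
    fixation_bounds_s: tuple[float, float] = (1.5, 60.0)
    amplitude_medians_deg: tuple[float, float] = (8.0, 13.0)  # (same, opposite)
    amplitude_sigma: float = 0.3
    amplitude_bounds_deg: tuple[float, float] = (2.0, 28.0)
    saccade_rise_time_s: float = 0.15
    position_noise_deg: float = 0.0
    duration_s: float = 600.0
    seed: int = 0
    #: explicit fixation durations; overrides sampling when given
    fixation_durations: list[float] | None = None
    #: quiet time before the first and after the last saccade when
    #: explicit fixation durations are given
    lead_s: float = 2.0

    def validate(self) -> None:
        if not (0.0 <= self.p_same_direction <= 1.0):
            raise ValueError("p_same_direction must lie in [0, 1]")
        if self.sample_rate_hz <= 0 or self.fixation_median_s <= 0:
            raise ValueError("rates and medians must be positive")
        if self.fixation_bounds_s[0] <= 0:
            raise ValueError("fixation durations must be strictly positive")
        if self.saccade_rise_time_s <= 0:
            raise ValueError("saccade_rise_time_s must be positive")
        if self.position_noise_deg < 0:
            raise ValueError("position_noise_deg must be nonnegative")


@dataclass
class SRCellConfig:
    """Parameters of a synthetic pre-saccadic rise (SR) cell.

    ``kappa`` is the common deconvolved-activity threshold reached at the
    time of each preferred-direction saccade; the per-fixation ramp slope
    is ``kappa / rise_duration`` up to multiplicative noise of coefficient
    of variation ``slope_noise_cv``.
    """

    kappa: float = 1.0
    preferred_direction: str = "L"
    slope_noise_cv: float = 0.0
    tau_s: float = 1.3
    noise_sd: float = 0.0
    ca_sample_rate_hz: float = 0.98
    baseline_f: float = 1.0
    rise_fraction_beta: tuple[float, float] = RISE_FRACTION_BETA
    seed: int = 0
    #: optional map fixation_index -> rise duration (s) before the
    #: upcoming saccade, overriding the Beta draw for those fixations
    forced_rise_durations: dict[int, float] | None = None

    def validate(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.preferred_direction not in ("L", "R"):
            raise ValueError("preferred_direction must be 'L' or 'R'")
        if self.slope_noise_cv < 0 or self.noise_sd < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.tau_s <= 0 or self.ca_sample_rate_hz <= 0:
            raise ValueError("tau_s and ca_sample_rate_hz must be positive")


@dataclass(frozen=True)
class RiseTruth:
    """Ground truth for one pre-saccadic rise event."""

    fixation_index: int
    onset_s: float
    slope: float
    rise_duration_s: float
    saccade_time_s: float


@dataclass
class GroundTruth:
    """Ground truth of a simulated behavior session.

    ``directions`` uses +1 for rightward, -1 for leftward saccades and
    aligns one-to-one with ``saccade_times_s``.
    """

    saccade_times_s: np.ndarray
    directions: np.ndarray
    amplitudes_deg: np.ndarray
    duration_s: float
    sr_events: dict[str, list[RiseTruth]] = field(default_factory=dict)
    archetypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.saccade_times_s = np.asarray(self.saccade_times_s, dtype=float)
        self.directions = np.asarray(self.directions, dtype=int)
        self.amplitudes_deg = np.asarray(self.amplitudes_deg, dtype=float)
        if self.directions.shape != self.saccade_times_s.shape:
            raise ValueError("directions must align with saccade_times_s")

    @property
    def fixation_durations_s(self) -> np.ndarray:
        return np.diff(self.saccade_times_s)

    @property
    def direction_labels(self) -> np.ndarray:
        return np.where(self.directions > 0, "R", "L")

    def to_json(self) -> str:
        payload = {
            "saccade_times_s": self.saccade_times_s.tolist(),
            "directions": self.directions.tolist(),
            "amplitudes_deg": self.amplitudes_deg.tolist(),
            "duration_s": self.duration_s,
            "sr_events": {
                cid: [asdict(ev) for ev in evs] for cid, evs in self.sr_events.items()
            },
            "archetypes": dict(self.archetypes),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        truth = cls(
            saccade_times_s=np.array(d["saccade_times_s"]),
            directions=np.array(d["directions"]),
            amplitudes_deg=np.array(d["amplitudes_deg"]),
            duration_s=float(d["duration_s"]),
        )
        truth.sr_events = {
            cid: [RiseTruth(**ev) for ev in evs] for cid, evs in d["sr_events"].items()
        }
        truth.archetypes = dict(d["archetypes"])
        return truth


def _truncated_lognormal(
    rng: np.random.Generator,
    median: float,
    sigma: float,
    bounds: tuple[float, float],
    size: int,
) -> np.ndarray:
    """Log-normal samples parameterized by median, rejected outside bounds."""
    lo, hi = bounds
    out = np.empty(size)
    filled = 0
    mu = np.log(median)
    while filled < size:
        draw = rng.lognormal(mu, sigma, size=2 * (size - filled) + 16)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _direction_sequence(
    rng: np.random.Generator, n: int, p_same: float
) -> np.ndarray:
    d = np.empty(n, dtype=int)
    d[0] = rng.choice([-1, 1])
    same = rng.random(n - 1) < p_same
    for k in range(1, n):
        d[k] = d[k - 1] if same[k - 1] else -d[k - 1]
    return d


def gen_eye_trace(cfg: BehaviorConfig) -> tuple[EyeTrace, GroundTruth]:
    """Simulate a horizontal eye-position trace with its ground truth.

    The trace is piecewise constant during fixations with fast linear
    ramps (``saccade_rise_time_s`` long) at saccades, plus optional
    Gaussian position noise.  Saccade times in the ground truth are the
    ramp onsets.  Raises ``ValueError`` if the requested duration cannot
    hold at least one complete fixation (two saccades).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    if cfg.fixation_durations is not None:
        fix = np.asarray(cfg.fixation_durations, dtype=float)
        if fix.size < 1 or np.any(fix <= 0):
            raise ValueError("explicit fixation durations must be positive")
        saccade_times = cfg.lead_s + np.concatenate([[0.0], np.cumsum(fix)])
        duration_s = float(saccade_times[-1] + cfg.lead_s)
    else:
        duration_s = float(cfg.duration_s)
        times = []
        t = float(
            _truncated_lognormal(
                rng, cfg.fixation_median_s, cfg.fixation_sigma, cfg.fixation_bounds_s, 1
            )[0]
        )
        while t < duration_s - cfg.lead_s:
            times.append(t)
            t += float(
                _truncated_lognormal(
                    rng,
                    cfg.fixation_median_s,
                    cfg.fixation_sigma,
                    cfg.fixation_bounds_s,
                    1,
                )[0]
            )
        if len(times) < 2:
            raise ValueError(
                "duration_s too short for one complete fixation; increase duration_s"
            )
        saccade_times = np.asarray(times)

    n = saccade_times.size
    directions = _direction_sequence(rng, n, cfg.p_same_direction)
    same_prev = np.concatenate([[False], directions[1:] == directions[:-1]])
    med_same, med_opp = cfg.amplitude_medians_deg
    amplitudes = np.where(
        same_prev,
        _truncated_lognormal(
            rng, med_same, cfg.amplitude_sigma, cfg.amplitude_bounds_deg, n
        ),
        _truncated_lognormal(
            rng, med_opp, cfg.amplitude_sigma, cfg.amplitude_bounds_deg, n
        ),
    )

    # knot points of the piecewise-linear position signal
    knot_t = [0.0]
    knot_p = [0.0]
    pos = 0.0
    for t_k, d_k, a_k in zip(saccade_times, directions, amplitudes):
        knot_t.append(t_k)
        knot_p.append(pos)
        pos += d_k * a_k
        knot_t.append(t_k + cfg.saccade_rise_time_s)
        knot_p.append(pos)
    knot_t.append(duration_s)
    knot_p.append(pos)

    time_s = np.arange(0.0, duration_s, 1.0 / cfg.sample_rate_hz)
    position = np.interp(time_s, knot_t, knot_p)
    if cfg.position_noise_deg > 0:
        position = position + rng.normal(0.0, cfg.position_noise_deg, time_s.size)

    trace = EyeTrace(time_s, position, eye_label="left")
    truth = GroundTruth(
        saccade_times_s=saccade_times,
        directions=directions,
        amplitudes_deg=amplitudes,
        duration_s=duration_s,
    )
    return trace, truth


def _calcium_kernel_filter(deconv: np.ndarray, dt: float, tau_s: float) -> np.ndarray:
    """Discrete exponential-kernel convolution via the AR(1) recursion.

    ``F[n] = g F[n-1] + deconv[n]`` with ``g = exp(-dt/tau)``, which equals
    the convolution of the deconvolved activity with the sampled kernel
    ``exp(-k dt / tau)``.
    """
    g = np.exp(-dt / tau_s)
    from scipy.signal import lfilter

    return lfilter([1.0], [1.0, -g], deconv)


def gen_sr_cell(
    cfg: SRCellConfig, truth: GroundTruth, cell_id: str = "sr0"
) -> CellTrace:
    """Simulate an SR cell obeying ramp-to-threshold structure.

    For every fixation whose *ending* saccade is in the preferred
    direction, deconvolved activity ramps linearly from a rise onset to
    the saccade, reaching ``kappa`` (up to slope noise) at the saccade;
    it is zero elsewhere.  Fluorescence is the ramp convolved with an
    exponential kernel of time constant ``tau_s`` plus a baseline and
    Gaussian noise.  The per-fixation onsets and slopes are recorded in
    ``truth.sr_events[cell_id]``.
    """
    cfg.validate()
    if truth.saccade_times_s.size < 2:
        raise ValueError("ground truth must contain at least one fixation")
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.ca_sample_rate_hz
    time_s = np.arange(0.0, truth.duration_s, dt)
    deconv = np.zeros_like(time_s)
    preferred = 1 if cfg.preferred_direction == "R" else -1
    a, b = cfg.rise_fraction_beta

    events: list[RiseTruth] = []
    sacc = truth.saccade_times_s
    for k in range(sacc.size - 1):
        # fixation k spans [sacc[k], sacc[k+1]] and ends with saccade k+1
        if truth.directions[k + 1] != preferred:
            continue
        f_dur = sacc[k + 1] - sacc[k]
        forced = (cfg.forced_rise_durations or {}).get(k)
        if forced is not None:
            rise = min(float(forced), f_dur)
        else:
            rise = min(max(float(rng.beta(a, b)) * f_dur, 2.0 * dt), f_dur)
        onset = sacc[k + 1] - rise
        slope = cfg.kappa / rise
        if cfg.slope_noise_cv > 0:
            slope *= max(1.0 + cfg.slope_noise_cv * rng.normal(), 0.05)
        mask = (time_s >= onset) & (time_s <= sacc[k + 1])
        deconv[mask] = slope * (time_s[mask] - onset)
        events.append(
            RiseTruth(
                fixation_index=k,
                onset_s=float(onset),
                slope=float(slope),
                rise_duration_s=rise,
                saccade_time_s=float(sacc[k + 1]),
            )
        )
    deconv = np.clip(deconv, 0.0, None)
    f = _calcium_kernel_filter(deconv, dt, cfg.tau_s) + cfg.baseline_f
    if cfg.noise_sd > 0:
        f = f + rng.normal(0.0, cfg.noise_sd, f.size)
    truth.sr_events[cell_id] = events
    truth.archetypes[cell_id] = "sr"
    xyz = rng.uniform([0.0, 0.0, 0.0], [185.0, 185.0, 60.0])
    return CellTrace(time_s=time_s, F=f, deconv=deconv, xyz_um=xyz, cell_id=cell_id)


def gen_archetype_cell(
    kind: str,
    direction: str,
    truth: GroundTruth,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 1.0,
    tau_s: float = 1.3,
    ca_sample_rate_hz: float = 0.98,
    baseline_f: float = 1.0,
    cell_id: str | None = None,
) -> CellTrace:
    """Simulate a tonic, burst, or burst-tonic cell.

    Deconvolved templates: ``tonic`` is zero before and constant after
    each preferred-direction saccade (until the next saccade); ``burst``
    is an impulse in the saccade-containing sample; ``burst_tonic`` is
    the sum of both.
    """
    if kind not in ("tonic", "burst", "burst_tonic"):
        raise ValueError(f"unknown archetype kind: {kind!r}")
    if direction not in ("L", "R"):
        raise ValueError("direction must be 'L' or 'R'")
    rng = np.random.default_rng(seed)
    dt = 1.0 / ca_sample_rate_hz
    time_s = np.arange(0.0, truth.duration_s, dt)
    deconv = np.zeros_like(time_s)
    preferred = 1 if direction == "R" else -1
    sacc = truth.saccade_times_s
    for k, (t_k, d_k) in enumerate(zip(sacc, truth.directions)):
        if d_k != preferred:
            continue
        t_next = sacc[k + 1] if k + 1 < sacc.size else truth.duration_s
        if kind in ("tonic", "burst_tonic"):
            deconv[(time_s >= t_k) & (time_s < t_next)] = amplitude
        if kind in ("burst", "burst_tonic"):
            idx = int(np.argmin(np.abs(time_s - t_k)))
            deconv[idx] += 3.0 * amplitude
    f = _calcium_kernel_filter(deconv, dt, tau_s) + baseline_f
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, f.size)
    cid = cell_id or f"{kind}0"
    truth.archetypes[cid] = kind
    xyz = rng.uniform([0.0, 0.0, 0.0], [185.0, 185.0, 60.0])
    return CellTrace(time_s=time_s, F=f, deconv=deconv, xyz_um=xyz, cell_id=cid)


def gen_frames(
    base_image: np.ndarray,
    shifts: np.ndarray,
    corrupt_frames: set[int] | tuple[int, ...] = (),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Build a frame stack by translating a base image.

    Frame ``k`` is ``base_image`` translated by ``shifts[k]`` (row, col)
    plus Gaussian noise; frames listed in ``corrupt_frames`` are replaced
    by a structured distortion (random per-row shear) emulating body
    movement.  Shifts larger than half the frame raise ``ValueError``.
    """
    base = np.asarray(base_image, dtype=float)
    shifts = np.atleast_2d(np.asarray(shifts, dtype=float))
    if not np.all(np.isfinite(shifts)):
        raise ValueError("shifts must be finite")
    half = np.array(base.shape) / 2.0
    if np.any(np.abs(shifts) > half):
        raise ValueError("shift larger than half the frame")
    rng = np.random.default_rng(seed)
    corrupt = set(int(k) for k in corrupt_frames)
    frames = np.empty((shifts.shape[0],) + base.shape, dtype=float)
    for k in range(shifts.shape[0]):
        if k in corrupt:
            sheared = base.copy()
            offsets = rng.integers(-base.shape[1] // 3, base.shape[1] // 3, base.shape[0])
            for r in range(base.shape[0]):
                sheared[r] = np.roll(sheared[r], offsets[r])
            frames[k] = sheared
        else:
            frames[k] = ndimage.shift(base, shifts[k], order=1, mode="nearest")
        if noise_sd > 0:
            frames[k] += rng.normal(0.0, noise_sd, base.shape)
    return frames


def gen_intensity_image(
    n_nuclei: int,
    shape: tuple[int, int] = (128, 128),
    radius_px: int = 5,
    min_separation_px: float = 12.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    peak: float = 150.0,
    background: float = 10.0,
    max_tries: int = 20000,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a time-averaged intensity image with disk-shaped nuclei.

    Returns an integer-valued image (as produced by averaging grayscale
    TIFF frames) and the ``(n, 2)`` array of true nucleus centers
    (row, col).  Raises ``RuntimeError`` if the nuclei cannot be placed
    at the requested separation after bounded retries.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = radius_px + 2
    if n_nuclei > 0 and (h <= 2 * margin or w <= 2 * margin):
        raise RuntimeError("frame too small for the requested nuclei")
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_nuclei:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place nuclei without overlap; "
                "reduce n_nuclei or min_separation_px"
            )
        cand = rng.uniform([margin, margin], [h - margin, w - margin])
        if all(np.hypot(*(cand - c)) >= min_separation_px for c in centers):
            centers.append(cand)
    image = np.full(shape, background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for c in centers:
        disk = np.hypot(yy - c[0], xx - c[1]) <= radius_px
        image[disk] = background + peak
    if noise_sd > 0:
        image += rng.normal(0.0, noise_sd, shape)
    image = np.clip(np.round(image), 0, None)
    return image, np.array(centers).reshape(-1, 2)


def gen_population_rise_traces(
    fixation_duration_s: float,
    n_traces: int,
    dt: float = 1.0 / 3.0,
    kappa: float = 1.0,
    rise_fraction_beta: tuple[float, float] = RISE_FRACTION_BETA,
    slope_noise_cv: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated single-fixation SR rise traces at a fixed fixation duration.

    Each trace lies on a 1/3-s grid whose last sample is at the saccade
    and ramps linearly from a Beta-distributed rise onset to ``kappa``,
    emulating the per-fixation interpolated activity that is averaged
    into population traces for the ramp-to-threshold analysis.  Returns
    ``(traces, slopes)`` with ``traces`` of shape ``n_traces x T``.
    """
    rng = np.random.default_rng(seed)
    a, b = rise_fraction_beta
    T = int(np.floor(fixation_duration_s / dt)) + 1
    time_before = dt * np.arange(T)[::-1]
    traces = np.zeros((n_traces, T))
    slopes = np.empty(n_traces)
    for i in range(n_traces):
        rise = max(float(rng.beta(a, b)) * fixation_duration_s, 2.0 * dt)
        slope = kappa / rise
        if slope_noise_cv > 0:
            slope *= max(1.0 + slope_noise_cv * rng.normal(), 0.05)
        slopes[i] = slope
        ramp = np.clip(slope * (rise - time_before), 0.0, None)
        ramp[time_before > rise] = 0.0
        traces[i] = ramp
    if noise_sd > 0:
        traces += rng.normal(0.0, noise_sd, traces.shape)
        traces = np.clip(traces, 0.0, None)
    return traces, slopes


def gen_ablation_experiments(
    effects: np.ndarray,
    n_before: int | tuple[int, int] = (60, 200),
    n_after: int | tuple[int, int] = (60, 200),
    group: str = "cluster",
    median_before_s: float = 11.4,
    sigma: float = FIXATION_SIGMA,
    seed: int = 0,
    lesion_centers_um: np.ndarray | None = None,
) -> list[AblationExperiment]:
    """Simulate per-animal before/after fixation-duration records.

    ``effects[j]`` is the true fractional change in median fixation
    duration for animal ``j``: post-ablation durations are drawn from a
    log-normal whose median is ``median_before_s * (1 + effects[j])``.
    """
    rng = np.random.default_rng(seed)
    effects = np.asarray(effects, dtype=float)

    def _count(spec_n):
        if isinstance(spec_n, tuple):
            return int(rng.integers(spec_n[0], spec_n[1] + 1))
        return int(spec_n)

    out = []
    for j, eff in enumerate(effects):
        nb, na = _count(n_before), _count(n_after)
        before = rng.lognormal(np.log(median_before_s), sigma, nb)
        after = rng.lognormal(np.log(median_before_s * (1.0 + eff)), sigma, na)
        center = None if lesion_centers_um is None else np.asarray(lesion_centers_um[j])
        out.append(
            AblationExperiment(
                animal_id=f"fish{j:02d}",
                group=group,
                fixations_before=before,
                fixations_after=after,
                lesion_center_um=center,
            )
        )
    return out


def gen_sr_map(
    n_points: int,
    bounds_um: tuple[tuple[float, float], ...] = ((0, 400), (0, 120), (0, 120)),
    fish_count_range: tuple[int, int] = (3, 8),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a registered SR-cell location map with per-point fish counts."""
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds_um], dtype=float)
    hi = np.array([b[1] for b in bounds_um], dtype=float)
    points = rng.uniform(lo, hi, size=(n_points, 3))
    counts = rng.integers(fish_count_range[0], fish_count_range[1] + 1, n_points)
    return points, counts
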