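"""Pre-saccadic rise (SR) cells and the ramp-to-threshold saccade-time model.

SR cells are eye-movement responsive neurons whose dF/F climbs toward an
upcoming saccade in a preferred direction; they are selected by a
one-sided Spearman correlation between activity and time relative to the
upcoming saccade (Holm-Bonferroni corrected).  Per fixation, the rise
onset is the last sample before deconvolved activity exceeds a
near-zero threshold, and the ramp slope is the least-squares line from
onset to saccade.  Under the ramp-to-threshold model, activity y = D*t
triggers a saccade when it reaches a common bound kappa, so the
remaining time is kappa/D - t; a running median-of-derivatives estimate
of D turns population activity into an online saccade-time prediction.
Choice probability (ROC area) quantifies how well pre-saccadic activity
separates upcoming left from right saccades, and ideal-observer
baselines bound what behavioral statistics alone can predict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import FixationInterval
from .sta_analysis import CellTrace, holm_bonferroni

__all__ = [
    "RiseEvent",
    "RampModel",
    "RampPrediction",
    "CPCurve",
    "FixationActivity",
    "select_sr_cells",
    "measure_rise_time",
    "measure_slope",
    "roc_area",
    "interpolate_fixation_activity",
    "choice_probability",
    "ramp_predict",
    "evaluate_ramp_model",
    "ramp_holdout_cc",
    "ideal_observer_direction",
    "empirical_opposite_guess_accuracy",
    "ideal_observer_timing",
]

#: interpolation bin for pre-saccadic activity grids (s)
DT_S = 1.0 / 3.0

#: deconvolved-activity rise threshold on the scale of the deposited
#: recordings; for synthetic data express it as a fraction of kappa
DEFAULT_RISE_THRESHOLD = 0.1

#: population-derivative onset threshold on the same recording scale
DEFAULT_DERIVATIVE_THRESHOLD = 35.0

#: post-saccadic window excluded from the Spearman selection (s)
POST_SACCADE_EXCLUSION_S = 2.0


@dataclass
class RiseEvent:
    """Timing and slope of one pre-saccadic rise within one fixation."""

    cell_id: str
    fixation_start_s: float
    fixation_end_s: float
    onset_s: float
    slope: float = np.nan
    slope_fit_cc: float = np.nan
    deconv_at_saccade: float = np.nan

    @property
    def rise_time_before_saccade_s(self) -> float:
        return self.fixation_end_s - self.onset_s

    @property
    def rise_time_after_previous_s(self) -> float:
        return self.onset_s - self.fixation_start_s

    @property
    def normalized_rise(self) -> float:
        """Onset relative to the upcoming saccade divided by fixation
        duration; lies in [-1, 0]."""
        dur = self.fixation_end_s - self.fixation_start_s
        return -self.rise_time_before_saccade_s / dur


def select_sr_cells(
    cells: list[CellTrace],
    events,
    alpha: float = 0.01,
    exclusion_s: float = POST_SACCADE_EXCLUSION_S,
    min_samples: int = 10,
) -> pd.DataFrame:
    """Select SR cells by Spearman correlation with time to upcoming saccade.

    Per direction, each cell's dF/F samples from all fixations ending in
    a saccade of that direction are paired with time relative to that
    saccade (negative, increasing toward 0); samples within
    ``exclusion_s`` of the previous saccade are dropped to avoid
    post-saccadic decays.  A one-sided test of rho > 0 is corrected with
    Holm-Bonferroni over ``2 x n_cells`` comparisons.  Cells significant
    in both directions are flagged bidirectional and excluded from
    downstream SR analyses.
    """
    times = np.array([e.onset_time_s for e in events])
    dirs = np.array([e.direction for e in events])
    records = []
    for cell in cells:
        rec = {"cell_id": cell.cell_id}
        for d in ("L", "R"):
            vals, rels = [], []
            for k in range(len(events) - 1):
                if dirs[k + 1] != d:
                    continue
                start, end = times[k], times[k + 1]
                mask = (cell.time_s > start + exclusion_s) & (cell.time_s <= end)
                vals.append(cell.dFF[mask])
                rels.append(cell.time_s[mask] - end)
            vals = np.concatenate(vals) if vals else np.empty(0)
            rels = np.concatenate(rels) if rels else np.empty(0)
            ok = np.isfinite(vals)
            if ok.sum() < min_samples:
                rec[f"rho_{d}"], rec[f"p_{d}"] = np.nan, np.nan
                continue
            res = stats.spearmanr(vals[ok], rels[ok], alternative="greater")
            rec[f"rho_{d}"], rec[f"p_{d}"] = float(res.statistic), float(res.pvalue)
        records.append(rec)
    df = pd.DataFrame(records)
    n_comparisons = 2 * len(df)
    pvals = np.concatenate([df["p_L"].to_numpy(), df["p_R"].to_numpy()])
    reject = holm_bonferroni(pvals, alpha=alpha, n_comparisons=n_comparisons)
    n = len(df)
    df["sig_L"] = reject[:n]
    df["sig_R"] = reject[n:]
    df["bidirectional_flag"] = df["sig_L"] & df["sig_R"]
    df["sr_flag"] = (df["sig_L"] | df["sig_R"]) & ~df["bidirectional_flag"]
    df["preferred_direction"] = np.where(
        df["sig_L"], "L", np.where(df["sig_R"], "R", "")
    )
    return df


def measure_rise_time(
    cell: CellTrace,
    fixation: FixationInterval,
    threshold: float = DEFAULT_RISE_THRESHOLD,
) -> RiseEvent | None:
    """Rise onset within one fixation: the time point before deconvolved
    activity first exceeds ``threshold``.  Returns ``None`` when activity
    never crosses the threshold inside the fixation."""
    t = cell.time_s
    in_fix = (t >= fixation.start_s) & (t <= fixation.end_s)
    idx = np.flatnonzero(in_fix & (cell.deconv > threshold))
    if idx.size == 0:
        return None
    first = idx[0]
    onset = t[first - 1] if first > 0 else t[first]
    onset = max(float(onset), fixation.start_s)
    # activity reached at the saccade: the last sample at or before it
    # (interpolating across the post-saccadic reset would bias it low)
    last = int(np.searchsorted(t, fixation.end_s, side="right")) - 1
    at_sacc = float(cell.deconv[last])
    return RiseEvent(
        cell_id=cell.cell_id,
        fixation_start_s=fixation.start_s,
        fixation_end_s=fixation.end_s,
        onset_s=onset,
        deconv_at_saccade=at_sacc,
    )


def measure_slope(
    cell: CellTrace, onset_s: float, saccade_time_s: float
) -> tuple[float, float] | None:
    """Least-squares slope of deconvolved activity from rise onset to saccade.

    Returns ``(slope, fit_cc)`` where ``fit_cc`` is the correlation
    between the regression line and the data (events with cc <= 0.4 are
    excluded downstream), or ``None`` with fewer than 3 samples.
    """
    mask = (cell.time_s >= onset_s) & (cell.time_s <= saccade_time_s)
    t, y = cell.time_s[mask], cell.deconv[mask]
    if t.size < 3:
        return None
    slope, intercept = np.polyfit(t, y, 1)
    fitted = slope * t + intercept
    if np.std(fitted) == 0 or np.std(y) == 0:
        return float(slope), 0.0
    cc = float(np.corrcoef(fitted, y)[0, 1])
    return float(slope), cc


def roc_area(signal: np.ndarray, noise: np.ndarray) -> float:
    """ROC area (choice probability) between two value distributions.

    Equivalent to the normalized rank-sum statistic: the fraction of
    (signal, noise) pairs with signal > noise, ties counted one half.
    0.5 means the distributions are indistinguishable.
    """
    signal = np.asarray(signal, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if signal.size == 0 or noise.size == 0:
        return np.nan
    u = stats.mannwhitneyu(signal, noise, alternative="two-sided").statistic
    return float(u / (signal.size * noise.size))


@dataclass
class FixationActivity:
    """One cell's interpolated activity across one fixation.

    ``values`` lie on a 1/3-s grid whose last sample is at the upcoming
    saccade; ``end_direction`` is that saccade's direction.
    """

    duration_s: float
    end_direction: str
    values: np.ndarray

    def value_at_time_before(self, seconds_before: float, dt: float = DT_S) -> float:
        k = int(round(seconds_before / dt))
        if k >= self.values.size:
            return np.nan
        return float(self.values[-1 - k])


def interpolate_fixation_activity(
    cell: CellTrace, fixation: FixationInterval, dt: float = DT_S
) -> FixationActivity:
    """Linearly interpolate deconvolved activity onto a 1/3-s grid from
    the previous to the upcoming saccade (last grid point at the saccade)."""
    n = int(np.floor(fixation.duration_s / dt)) + 1
    grid = fixation.end_s - dt * np.arange(n)[::-1]
    values = np.interp(grid, cell.time_s, cell.deconv)
    return FixationActivity(
        duration_s=fixation.duration_s,
        end_direction=fixation.following_direction,
        values=values,
    )


@dataclass
class CPCurve:
    """Choice probability as a function of time before the saccade."""

    times_before_s: np.ndarray
    cp: np.ndarray
    sem: np.ndarray
    pool_size: int


def choice_probability(
    cell_activity: dict[str, tuple[str, list[FixationActivity]]],
    pool_size: int = 1,
    max_time_s: float = 5.0,
    dt: float = DT_S,
    duration_condition_s: range = range(2, 21),
    n_group_resamples: int = 100,
    seed: int = 0,
) -> CPCurve:
    """Choice probability of upcoming saccade direction from SR activity.

    ``cell_activity`` maps cell id to ``(preferred_direction,
    fixation_activities)``.  At each time before the saccade, the signal
    distribution holds activity before preferred-direction saccades and
    the noise distribution activity before opposite saccades; CP is the
    ROC area between them.  For ``pool_size > 1``, cells with a common
    preferred direction are randomly grouped (``n_group_resamples``
    regroupings) and each group's per-fixation average is used instead.
    The SEM is taken across CPs conditioned on fixation duration
    (``duration_condition_s``, within 0.5 s).
    """
    if len(cell_activity) < 2:
        raise ValueError("need at least 2 SR cells")
    rng = np.random.default_rng(seed)
    times = dt * np.arange(1, int(round(max_time_s / dt)) + 1)

    def _groups() -> list[list[str]]:
        if pool_size == 1:
            return [[cid] for cid in cell_activity]
        groups = []
        for d in ("L", "R"):
            ids = [cid for cid, (pref, _) in cell_activity.items() if pref == d]
            perm = list(rng.permutation(ids))
            groups += [
                perm[i : i + pool_size]
                for i in range(0, len(perm) - pool_size + 1, pool_size)
            ]
        return groups

    def _pooled_values(groups, duration_sel=None):
        """signal/noise values per time index for a set of cell groups."""
        sig = [[] for _ in times]
        noi = [[] for _ in times]
        for group in groups:
            pref = cell_activity[group[0]][0]
            fixes = [cell_activity[cid][1] for cid in group]
            for fi in range(len(fixes[0])):
                fx0 = fixes[0][fi]
                if duration_sel is not None and abs(fx0.duration_s - duration_sel) > 0.5:
                    continue
                for ti, s in enumerate(times):
                    vals = [fx[fi].value_at_time_before(s, dt) for fx in fixes]
                    if np.any(np.isnan(vals)):
                        continue
                    v = float(np.mean(vals))
                    (sig if fx0.end_direction == pref else noi)[ti].append(v)
        return sig, noi

    n_rounds = 1 if pool_size == 1 else n_group_resamples
    cp_rounds = np.full((n_rounds, times.size), np.nan)
    for r in range(n_rounds):
        sig, noi = _pooled_values(_groups())
        for ti in range(times.size):
            cp_rounds[r, ti] = roc_area(np.array(sig[ti]), np.array(noi[ti]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        cp = np.nanmean(cp_rounds, axis=0)

    # variability across fixation-duration-conditioned CPs
    groups = _groups()
    cond = np.full((len(duration_condition_s), times.size), np.nan)
    for di, d in enumerate(duration_condition_s):
        sig, noi = _pooled_values(groups, duration_sel=float(d))
        for ti in range(times.size):
            cond[di, ti] = roc_area(np.array(sig[ti]), np.array(noi[ti]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        n_ok = np.sum(np.isfinite(cond), axis=0)
        sem = np.nanstd(cond, axis=0, ddof=1) / np.sqrt(np.maximum(n_ok, 1))
    return CPCurve(times_before_s=times, cp=cp, sem=sem, pool_size=pool_size)


@dataclass
class RampModel:
    """Ramp-to-threshold model parameters.

    ``kappa`` is the activity bound (mean deconvolved activity at the
    time of saccade across SR cells); ``derivative_threshold`` detects
    the population rise onset; both are on the scale of the data being
    analyzed (the printed defaults apply to the deposited recordings —
    rescale proportionally to kappa for other units).
    """

    kappa: float
    dt: float = DT_S
    derivative_threshold: float = DEFAULT_DERIVATIVE_THRESHOLD

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.dt <= 0:
            raise ValueError("kappa and dt must be positive")


@dataclass
class RampPrediction:
    """Online predictions for one population trace (saccade at the last sample)."""

    onset_index: int
    t_since_onset_s: np.ndarray
    predicted_remaining_s: np.ndarray
    actual_remaining_s: np.ndarray


def estimate_kappa(deconv_at_saccade: np.ndarray) -> float:
    """Threshold estimate: mean deconvolved activity at saccade across
    SR cells and fixations."""
    vals = np.asarray(deconv_at_saccade, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no activity-at-saccade samples")
    return float(vals.mean())


def derivative_threshold_from_slopes(slopes: np.ndarray, ratio: float = 0.1) -> float:
    """Scale the population-rise onset threshold to arbitrary activity units.

    On the deposited recordings the onset threshold (35 a.u./s) is about
    one tenth of the mean single-event ramp slope (365 a.u./s); this
    helper applies that ratio to the mean of the measured slopes, giving
    a threshold that carries no assumption about the recording's units.
    """
    slopes = np.asarray(slopes, dtype=float)
    slopes = slopes[np.isfinite(slopes)]
    if slopes.size == 0:
        raise ValueError("no slope measurements")
    return float(ratio * slopes.mean())


def ramp_predict(population_trace: np.ndarray, model: RampModel) -> RampPrediction | None:
    """Online saccade-time prediction from a population activity trace.

    ``population_trace`` is the average interpolated SR activity on the
    model's grid with the saccade at the final sample.  The rise onset
    (time 0) is the first finite-difference derivative exceeding the
    model's threshold; the running slope estimate D(t) is the median of
    the derivatives on (0, t], and the predicted remaining time is
    ``kappa / D(t) - t``, reported from one bin after onset to one bin
    before the saccade.  Returns ``None`` when the derivative never
    exceeds the threshold; predictions where D(t) <= 0 are NaN.
    """
    y = np.asarray(population_trace, dtype=float)
    if y.size < 3:
        return None
    d = np.diff(y) / model.dt
    above = np.flatnonzero(d > model.derivative_threshold)
    if above.size == 0:
        return None
    i0 = int(above[0])
    t_list, pred, actual = [], [], []
    n = y.size
    for j in range(i0 + 1, n - 1):
        t = (j - i0) * model.dt
        running = np.median(d[i0:j])
        if running > 0:
            p = model.kappa / running - t
        else:
            p = np.nan
        t_list.append(t)
        pred.append(p)
        actual.append((n - 1 - j) * model.dt)
    return RampPrediction(
        onset_index=i0,
        t_since_onset_s=np.array(t_list),
        predicted_remaining_s=np.array(pred),
        actual_remaining_s=np.array(actual),
    )


def evaluate_ramp_model(
    predictions: np.ndarray, actuals: np.ndarray
) -> tuple[float, float]:
    """Score predicted vs actual time-until-saccade.

    Returns ``(cc, timing_error_percent)``: the Pearson correlation and
    the median of ``|predicted - actual| / actual`` in percent.  Constant
    predictions give cc = 0 (zero variance) with a warning.
    """
    p = np.asarray(predictions, dtype=float)
    a = np.asarray(actuals, dtype=float)
    ok = np.isfinite(p) & np.isfinite(a) & (a > 0)
    p, a = p[ok], a[ok]
    if p.size < 3:
        raise ValueError("need at least 3 matched prediction/actual pairs")
    if np.std(p) == 0 or np.std(a) == 0:
        warnings.warn("zero-variance predictions; correlation undefined, set to 0")
        cc = 0.0
    else:
        cc = float(np.corrcoef(p, a)[0, 1])
    err = float(np.median(np.abs(p - a) / a) * 100.0)
    return cc, err


def ramp_holdout_cc(
    cell_traces: np.ndarray,
    kappa: float,
    dt: float = DT_S,
    train_fraction: float = 0.6,
    n_splits: int = 100,
    seed: int = 0,
) -> float:
    """Ramp-model fit quality with cell-level train/test splitting.

    ``cell_traces`` is ``n_cells x T`` interpolated pre-saccadic activity
    for one fixation duration (saccade at the last sample).  For each
    split, the slope D is the single whole-rise estimate (median
    derivative of the training-cell average), the model ``y = D t`` is
    evaluated against the held-out-cell average, and the Pearson
    correlation is returned averaged over splits.
    """
    X = np.asarray(cell_traces, dtype=float)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    n_train = max(1, int(round(train_fraction * n)))
    ccs = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        train = X[perm[:n_train]].mean(axis=0)
        test = X[perm[n_train:]].mean(axis=0)
        d_est = np.median(np.diff(train) / dt)
        if d_est <= 0:
            continue
        t = dt * np.arange(X.shape[1])
        model_y = d_est * t
        if np.std(test) == 0:
            continue
        ccs.append(np.corrcoef(model_y, test)[0, 1])
    if not ccs:
        raise ValueError("no valid splits")
    return float(np.mean(ccs))


def ideal_observer_direction(p_same: float) -> float:
    """Accuracy of always guessing the direction opposite the previous
    saccade: ``1 - p_same``."""
    if not (0.0 <= p_same <= 1.0):
        raise ValueError("p_same must lie in [0, 1]")
    return 1.0 - p_same


def empirical_opposite_guess_accuracy(directions) -> float:
    """Empirical accuracy of the always-guess-opposite rule on a
    direction sequence."""
    d = np.asarray(directions)
    if d.size < 2:
        raise ValueError("need at least two saccades")
    return float(np.mean(d[1:] != d[:-1]))


def ideal_observer_timing(
    fixation_durations: np.ndarray,
    elapsed_s: float,
    cost: str = "all_or_none",
    bin_s: float = 0.5,
) -> float:
    """Optimal remaining-time guess from the fixation-duration distribution.

    Conditions the duration sample on exceeding ``elapsed_s`` and returns
    the guess minimizing the chosen cost on the remaining time: the
    conditional mean (``"MSE"``), median (``"MAD"``), or the center of
    the modal ``bin_s`` histogram bin (``"all_or_none"``).
    """
    durations = np.asarray(fixation_durations, dtype=float)
    remaining = durations[durations > elapsed_s] - elapsed_s
    if remaining.size == 0:
        raise ValueError("no fixation durations exceed the elapsed time")
    cost = cost.lower()
    if cost == "mse":
        return float(remaining.mean())
    if cost == "mad":
        return float(np.median(remaining))
    if cost == "all_or_none":
        edges = np.arange(0.0, remaining.max() + 2 * bin_s, bin_s)
        counts, edges = np.histogram(remaining, bins=edges)
        k = int(np.argmax(counts))
        in_bin = remaining[(remaining >= edges[k]) & (remaining < edges[k + 1])]
        # representative value of the modal bin (its median), so a
        # degenerate distribution is predicted exactly
        return float(np.median(in_bin)) if in_bin.size else float(edges[k])
    raise ValueError(f"unknown cost: {cost!r}")
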