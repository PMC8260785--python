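"""Ablation-effect statistics on fixation durations.

After laser ablation of hindbrain cells, the behavioral effect is the
fractional change in median fixation duration.  Because the number of
recorded fixations differs across animals, effects are computed on
repeated equal-size resamples: with ``N_min`` the smallest fixation
count over all animals and both conditions, each animal contributes
``round(min_i n_ij / N_min)`` repeats, each drawing ``N_min`` durations
without replacement per condition and evaluating

    y = (median_after - median_before) / median_before.

This module also estimates the fraction of mapped pre-saccadic-rise (SR)
cells removed by a cylindrical lesion, bootstraps the correlation of
effect size against that fraction across sample-size floors, and
compares targeted ablation groups with rank-sum and t tests against a
sham built from non-ablated animals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AblationExperiment",
    "exclude_nonsaccading",
    "resample_effect",
    "effect_full_sample",
    "fraction_ablated",
    "correlate_effect_vs_fraction",
    "compare_targeted_groups",
    "sham_effects",
]


@dataclass
class AblationExperiment:
    """Fixation-duration record of one animal around an ablation."""

    animal_id: str
    group: str
    fixations_before: np.ndarray
    fixations_after: np.ndarray
    lesion_center_um: np.ndarray | None = None
    n_targeted: int = 0
    n_ablated: int = 0
    #: post-ablation saccade rate per direction (left, right), per minute
    saccade_rate_after_per_min: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.fixations_before = np.asarray(self.fixations_before, dtype=float)
        self.fixations_after = np.asarray(self.fixations_after, dtype=float)
        if np.any(self.fixations_before <= 0) or np.any(self.fixations_after <= 0):
            raise ValueError("fixation durations must be positive")

    @property
    def n_min_conditions(self) -> int:
        return min(self.fixations_before.size, self.fixations_after.size)


def exclude_nonsaccading(
    experiments: list[AblationExperiment], rate_floor_per_min: float = 1.0
) -> tuple[list[AblationExperiment], list[str]]:
    """Drop animals whose post-ablation saccade rate never rose above the
    floor (one saccade per direction per minute; the boundary itself is
    excluded).  Animals without rate metadata are retained.  Returns the
    filtered list and the ids of excluded animals."""
    kept, excluded = [], []
    for exp in experiments:
        rates = exp.saccade_rate_after_per_min
        if rates is not None and min(rates) <= rate_floor_per_min:
            excluded.append(exp.animal_id)
        else:
            kept.append(exp)
    return kept, excluded


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def global_n_min(experiments: list[AblationExperiment]) -> int:
    """Smallest fixation count over all animals and both conditions."""
    if not experiments:
        raise ValueError("no experiments")
    return min(
        min(e.fixations_before.size, e.fixations_after.size) for e in experiments
    )


def effect_full_sample(exp: AblationExperiment) -> float:
    """Plain fractional change in median fixation duration (no resampling)."""
    mb = np.median(exp.fixations_before)
    return float((np.median(exp.fixations_after) - mb) / mb)


def resample_effect(
    experiments: list[AblationExperiment],
    n_min: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Equal-sample resampled effect sizes.

    Returns one row per (animal, repeat) with the fractional change in
    median fixation duration computed from ``n_min`` durations sampled
    without replacement per condition.  An included animal contributes at
    least one repeat.
    """
    if not experiments:
        raise ValueError("no experiments")
    if n_min is None:
        n_min = global_n_min(experiments)
    if n_min < 1:
        raise ValueError("n_min must be at least 1")
    rng = np.random.default_rng(seed)
    rows = []
    for exp in experiments:
        avail = exp.n_min_conditions
        if avail < n_min:
            raise ValueError(
                f"animal {exp.animal_id} has fewer than n_min={n_min} fixations"
            )
        repeats = max(1, _round_half_away(avail / n_min))
        for rep in range(repeats):
            before = rng.choice(exp.fixations_before, size=n_min, replace=False)
            after = rng.choice(exp.fixations_after, size=n_min, replace=False)
            mb = np.median(before)
            rows.append(
                {
                    "animal_id": exp.animal_id,
                    "group": exp.group,
                    "repeat": rep,
                    "y": float((np.median(after) - mb) / mb),
                }
            )
    return pd.DataFrame(rows)


def fraction_ablated(
    map_points_um: np.ndarray,
    fish_counts: np.ndarray,
    lesion_center_um: np.ndarray,
    radius_um: float = 30.0,
    height_um: float = 60.0,
    subsample: bool = True,
    seed: int = 0,
) -> float:
    """Fraction of mapped SR cells inside the lesion cylinder.

    The cylinder has the given radius in the rostral-caudal /
    medial-lateral plane (first two coordinates) and extends
    ``height_um`` along the dorsal-ventral axis (third coordinate).  To
    correct for unequal sampling, each map point is first kept with
    probability ``3 / fish_count`` at its location.
    """
    pts = np.asarray(map_points_um, dtype=float).reshape(-1, 3)
    if pts.shape[0] == 0:
        raise ValueError("empty SR map")
    counts = np.broadcast_to(np.asarray(fish_counts, dtype=float), (pts.shape[0],))
    center = np.asarray(lesion_center_um, dtype=float)
    if subsample:
        rng = np.random.default_rng(seed)
        keep = rng.random(pts.shape[0]) < np.minimum(3.0 / counts, 1.0)
        if not keep.any():
            return 0.0
        pts = pts[keep]
    d = pts - center
    inside = (np.hypot(d[:, 0], d[:, 1]) <= radius_um) & (
        np.abs(d[:, 2]) <= height_um / 2.0
    )
    return float(inside.mean())


def correlate_effect_vs_fraction(
    experiments: list[AblationExperiment],
    fractions: dict[str, float],
    floors: range = range(55, 176, 10),
    n_boot: int = 100,
    alpha: float = 0.001,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Bootstrap correlation of ablation effect vs fraction of SR cells removed.

    For each sample-size floor, animals with fewer fixations than the
    floor in either condition are dropped, ``N_min`` is recomputed, and
    ``n_boot`` resampled effect vectors give ``n_boot`` Pearson
    correlation coefficients; the same with shuffled effects gives the
    null.  A one-sided two-sample KS test compares the two coefficient
    samples; the per-floor p-values are assessed with Holm-Bonferroni at
    ``alpha``.  Returns the per-floor table and the mean of the per-floor
    median correlations.
    """
    from .sta_analysis import holm_bonferroni

    rng = np.random.default_rng(seed)
    rows = []
    for floor in floors:
        kept = [e for e in experiments if e.n_min_conditions >= floor]
        if len(kept) < 5:
            warnings.warn(f"floor {floor}: fewer than 5 animals remain; skipped")
            continue
        n_min = global_n_min(kept)
        ccs = np.empty(n_boot)
        ccs_shuffled = np.empty(n_boot)
        for b in range(n_boot):
            eff = resample_effect(kept, n_min=n_min, seed=int(rng.integers(2**31)))
            y = eff["y"].to_numpy()
            x = eff["animal_id"].map(fractions).to_numpy(dtype=float)
            ccs[b] = stats.pearsonr(x, y).statistic
            ccs_shuffled[b] = stats.pearsonr(x, rng.permutation(y)).statistic
        # alternative="less": the empirical CDF of the real coefficients lies
        # below the shuffled one, i.e. real correlations are larger
        ks = stats.ks_2samp(ccs, ccs_shuffled, alternative="less")
        rows.append(
            {
                "floor": floor,
                "n_animals": len(kept),
                "n_min": n_min,
                "median_cc": float(np.median(ccs)),
                "ks_p": float(ks.pvalue),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["significant"] = holm_bonferroni(table["ks_p"].to_numpy(), alpha=alpha)
        mean_cc = float(table["median_cc"].mean())
    else:
        mean_cc = np.nan
    return table, mean_cc


def sham_effects(
    fixation_sets: list[np.ndarray], n_min: int = 33, seed: int = 0
) -> np.ndarray:
    """Sham effect sizes from non-ablated animals.

    Each animal's fixations are randomly split in half into pseudo
    before/after groups, from which ``n_min`` durations per condition are
    drawn without replacement and the fractional change in medians
    computed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for fx in fixation_sets:
        fx = np.asarray(fx, dtype=float)
        if fx.size < 2 * n_min:
            raise ValueError("need at least 2*n_min fixations per sham animal")
        perm = rng.permutation(fx)
        half = fx.size // 2
        before = rng.choice(perm[:half], size=n_min, replace=False)
        after = rng.choice(perm[half:], size=n_min, replace=False)
        mb = np.median(before)
        out.append((np.median(after) - mb) / mb)
    return np.array(out)


def compare_targeted_groups(
    sr_experiments: list[AblationExperiment],
    control_experiments: list[AblationExperiment],
    sham_fixation_sets: list[np.ndarray],
    n_runs: int = 100,
    n_min: int = 33,
    seed: int = 0,
) -> dict:
    """Compare SR-targeted, control-targeted, and sham ablation effects.

    Over ``n_runs`` resampling runs, reports the min/median/max of the
    one-sided rank-sum p-value (alternative: SR effects larger than
    control) and of each group's mean effect, plus two-sided t tests of
    each targeted group against the sham distribution with a Bonferroni
    correction.
    """
    if len(sr_experiments) < 2 or len(control_experiments) < 2:
        raise ValueError("need at least 2 animals per targeted group")
    rng = np.random.default_rng(seed)
    pvals, sr_means, ctl_means = [], [], []
    first_run: dict[str, np.ndarray] = {}
    for r in range(n_runs):
        s = int(rng.integers(2**31))
        y_sr = resample_effect(sr_experiments, n_min=n_min, seed=s)["y"].to_numpy()
        y_ctl = resample_effect(control_experiments, n_min=n_min, seed=s + 1)[
            "y"
        ].to_numpy()
        if np.ptp(y_sr) == 0 and np.ptp(y_ctl) == 0:
            warnings.warn("degenerate (all-identical) effect vectors")
        res = stats.mannwhitneyu(y_sr, y_ctl, alternative="greater")
        pvals.append(float(res.pvalue))
        sr_means.append(float(y_sr.mean()))
        ctl_means.append(float(y_ctl.mean()))
        if r == 0:
            first_run = {"sr": y_sr, "control": y_ctl}
    sham = sham_effects(sham_fixation_sets, n_min=n_min, seed=int(rng.integers(2**31)))
    t_sr = stats.ttest_ind(first_run["sr"], sham)
    t_ctl = stats.ttest_ind(first_run["control"], sham)
    bonf = 2.0
    return {
        "rank_sum_p": _min_med_max(pvals),
        "sr_mean_effect": _min_med_max(sr_means),
        "control_mean_effect": _min_med_max(ctl_means),
        "sham_mean_effect": float(sham.mean()),
        "sham_median_effect": float(np.median(sham)),
        "ttest_sr_vs_sham_p": min(float(t_sr.pvalue) * bonf, 1.0),
        "ttest_control_vs_sham_p": min(float(t_ctl.pvalue) * bonf, 1.0),
    }


def _min_med_max(values: list[float]) -> dict[str, float]:
    arr = np.asarray(values, dtype=float)
    return {
        "min": float(arr.min()),
        "median": float(np.median(arr)),
        "max": float(arr.max()),
    }
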