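"""Saccade-triggered averages, responsive-cell screening, and the functional map.

The saccade-triggered average (STA) of a cell is its activity linearly
interpolated onto a fixed grid of 31 time bins (1/3 s apart, spanning
5 s before to 5 s after the saccade) and averaged over qualifying
saccades of one direction.  Cells whose STA deviates from flatness under
a one-way ANOVA (Holm-Bonferroni corrected across cells and directions)
are "eye-movement responsive".  The population of responsive STAs is
embedded with PCA after L2 normalization; the first three coefficients,
renormalized to the unit sphere and expressed in spherical coordinates
(Phi, Theta), give a compact functional map that is clustered with
K-means using the silhouette criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

__all__ = [
    "STA_GRID",
    "CellTrace",
    "STAProfile",
    "CellSTA",
    "PCAEmbedding",
    "ClusterResult",
    "compute_dff",
    "compute_sta",
    "screen_responsive",
    "holm_bonferroni",
    "pca_embed",
    "spherical_coords",
    "population_average_by_phi",
    "kmeans_select_k",
]

#: time grid of the saccade-triggered average: 31 bins of 1/3 s, -5..+5 s
STA_GRID = np.linspace(-5.0, 5.0, 31)

#: minimum flanking fixation duration for a saccade to enter an STA (s)
MIN_FLANK_S = 5.0

#: minimum qualifying trials per direction for an eligible STA
MIN_TRIALS = 5


def compute_dff(F: np.ndarray) -> np.ndarray:
    """dF/F: raw fluorescence minus its recording mean, divided by that mean."""
    F = np.asarray(F, dtype=float)
    f0 = np.nanmean(F)
    if f0 == 0 or not np.isfinite(f0):
        raise ValueError("baseline F0 (mean fluorescence) must be nonzero")
    return (F - f0) / f0


@dataclass
class CellTrace:
    """One cell's fluorescence time series and location.

    ``dFF`` is derived from ``F`` on construction when not supplied;
    ``deconv`` is the nonnegative deconvolved activity estimate.
    """

    time_s: np.ndarray
    F: np.ndarray
    deconv: np.ndarray
    xyz_um: np.ndarray = field(default_factory=lambda: np.zeros(3))
    cell_id: str = "cell0"
    fish_id: str = "sim"
    plane_id: int = 0
    dFF: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.deconv = np.asarray(self.deconv, dtype=float)
        if not (self.time_s.size == self.F.size == self.deconv.size):
            raise ValueError("time_s, F, deconv must have equal length")
        if np.nanmin(self.deconv) < 0:
            raise ValueError("deconvolved activity must be nonnegative")
        if self.dFF is None:
            self.dFF = compute_dff(self.F)
        else:
            self.dFF = np.asarray(self.dFF, dtype=float)

    @property
    def F0(self) -> float:
        return float(np.nanmean(self.F))


@dataclass
class STAProfile:
    """Per-direction saccade-triggered trial matrix and average.

    ``trials`` is ``n_trials x 31`` on :data:`STA_GRID`; the 95% CI is a
    bootstrap over trials (100 resamples, 0.025/0.975 quantiles).  A
    profile with fewer than :data:`MIN_TRIALS` trials is ineligible.
    """

    direction: str
    trials: np.ndarray
    mean: np.ndarray = field(init=False)
    ci_low: np.ndarray = field(init=False)
    ci_high: np.ndarray = field(init=False)
    n_boot: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        if self.trials.shape[1] != STA_GRID.size:
            raise ValueError(f"trials must have {STA_GRID.size} time bins")
        self.mean = self.trials.mean(axis=0)
        rng = np.random.default_rng(self.seed)
        n = self.trials.shape[0]
        boots = np.empty((self.n_boot, STA_GRID.size))
        for b in range(self.n_boot):
            boots[b] = self.trials[rng.integers(0, n, n)].mean(axis=0)
        self.ci_low = np.quantile(boots, 0.025, axis=0)
        self.ci_high = np.quantile(boots, 0.975, axis=0)

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def eligible(self) -> bool:
        return self.n_trials >= MIN_TRIALS


@dataclass
class CellSTA:
    """A cell's pair of directional STA profiles (either may be missing)."""

    cell_id: str
    left: STAProfile | None
    right: STAProfile | None

    @property
    def eligible(self) -> bool:
        return (
            self.left is not None
            and self.right is not None
            and self.left.eligible
            and self.right.eligible
        )


def _qualifying_saccades(events, direction: str, min_flank_s: float) -> list[int]:
    times = np.array([e.onset_time_s for e in events])
    idx = []
    for k, e in enumerate(events):
        if e.direction != direction:
            continue
        if k == 0 or k == len(events) - 1:
            continue
        if times[k] - times[k - 1] >= min_flank_s and times[k + 1] - times[k] >= min_flank_s:
            idx.append(k)
    return idx


def compute_sta(
    cell: CellTrace,
    events,
    direction: str,
    signal: str = "dff",
    min_flank_s: float = MIN_FLANK_S,
    seed: int = 0,
) -> STAProfile | None:
    """Saccade-triggered average of one cell for one saccade direction.

    Qualifying saccades are preceded and followed by fixations of at
    least ``min_flank_s`` (default 5 s).  The chosen signal (``"dff"`` or
    ``"deconv"``) is linearly interpolated onto :data:`STA_GRID` around
    each qualifying saccade; trials whose window leaves the recording or
    contains masked (NaN) samples are dropped.  Returns ``None`` when no
    trial qualifies; the caller checks ``eligible`` for the >= 5-trial
    requirement.
    """
    y = cell.dFF if signal == "dff" else cell.deconv
    t = cell.time_s
    trials = []
    for k in _qualifying_saccades(events, direction, min_flank_s):
        t0 = events[k].onset_time_s
        if t0 + STA_GRID[0] < t[0] or t0 + STA_GRID[-1] > t[-1]:
            continue
        native = (t >= t0 + STA_GRID[0]) & (t <= t0 + STA_GRID[-1])
        if not np.all(np.isfinite(y[native])):
            continue
        trials.append(np.interp(t0 + STA_GRID, t, y))
    if not trials:
        return None
    return STAProfile(direction=direction, trials=np.array(trials), seed=seed)


def sta_anova_pvalue(profile: STAProfile) -> float:
    """One-way ANOVA p-value for the null that STA activity is equal at
    all 31 time bins (bins are groups, trials are replicates)."""
    groups = [profile.trials[:, t] for t in range(profile.trials.shape[1])]
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(profile.mean) == 0:
        return np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.f_oneway(*groups).pvalue)


def holm_bonferroni(
    pvals: np.ndarray, alpha: float = 0.01, n_comparisons: int | None = None
) -> np.ndarray:
    """Holm-Bonferroni step-down rejection mask.

    Sorted p-values are compared against ``alpha / (N - j + 1)`` where
    ``j`` is the 1-based sorted index; rejection stops at the first
    failure.  ``n_comparisons`` may exceed ``len(pvals)`` when some
    family members were not testable.  NaN p-values are never rejected.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    N = int(n_comparisons) if n_comparisons is not None else m
    if N < m:
        raise ValueError("n_comparisons must be >= number of p-values")
    reject = np.zeros(m, dtype=bool)
    order = np.argsort(np.where(np.isnan(p), np.inf, p))
    for j, idx in enumerate(order, start=1):
        pj = p[idx]
        if np.isnan(pj) or pj > alpha / (N - j + 1):
            break
        reject[idx] = True
    return reject


def screen_responsive(
    cell_stas: list[CellSTA],
    alpha: float = 0.01,
    peak_quantile: float = 0.01,
    peak_floor: float = 0.14,
    min_cells_for_quantile: int = 100,
) -> "pd.DataFrame":
    """Screen cells for eye-movement responsiveness.

    Per direction, a one-way ANOVA tests whether the STA differs across
    the 31 time bins; a cell is responsive iff either direction rejects
    under Holm-Bonferroni at family-wise ``alpha`` over ``2 x n_cells``
    comparisons.  Before testing, cells whose peak absolute mean STA lies
    in the dataset's bottom ``peak_quantile`` (or below the absolute
    ``peak_floor`` for small datasets) are dropped as near-silent.
    """
    import pandas as pd

    records = []
    for cs in cell_stas:
        peak = np.nan
        p_l = p_r = np.nan
        if cs.eligible:
            peak = max(
                np.max(np.abs(cs.left.mean)), np.max(np.abs(cs.right.mean))
            )
            p_l = sta_anova_pvalue(cs.left)
            p_r = sta_anova_pvalue(cs.right)
            if np.isnan(p_l) or np.isnan(p_r):
                warnings.warn(
                    f"cell {cs.cell_id}: degenerate (zero-variance) trials; excluded"
                )
        records.append(
            {"cell_id": cs.cell_id, "peak_abs_sta": peak, "p_left": p_l, "p_right": p_r}
        )
    df = pd.DataFrame(records)

    eligible = df["peak_abs_sta"].notna()
    if eligible.sum() >= min_cells_for_quantile:
        threshold = float(df.loc[eligible, "peak_abs_sta"].quantile(peak_quantile))
    else:
        threshold = peak_floor
    tested = eligible & (df["peak_abs_sta"] > threshold)

    n_comparisons = 2 * len(df)
    pvals = np.concatenate(
        [
            np.where(tested, df["p_left"], np.nan),
            np.where(tested, df["p_right"], np.nan),
        ]
    )
    reject = holm_bonferroni(pvals, alpha=alpha, n_comparisons=n_comparisons)
    n = len(df)
    df["reject_left"] = reject[:n]
    df["reject_right"] = reject[n:]
    df["tested"] = tested
    df["responsive"] = df["reject_left"] | df["reject_right"]
    return df


@dataclass
class PCAEmbedding:
    """PCA of L2-normalized STAs with spherical-coordinate summary.

    ``components`` are orthonormal 31-vectors with a fixed sign
    convention (the largest-magnitude element of each component is
    positive) so that the angles are reproducible across runs.
    ``coefficients`` reproduce the row-centered normalized data:
    ``normalized - mean = coefficients @ components``.
    """

    components: np.ndarray
    coefficients: np.ndarray
    variance_explained: np.ndarray
    mean: np.ndarray
    normalized: np.ndarray

    @property
    def normalized_coeffs3(self) -> np.ndarray:
        c3 = self.coefficients[:, :3]
        return c3 / np.linalg.norm(c3, axis=1, keepdims=True)

    @property
    def phi_deg(self) -> np.ndarray:
        return spherical_coords(self.coefficients[:, :3])[0]

    @property
    def theta_deg(self) -> np.ndarray:
        return spherical_coords(self.coefficients[:, :3])[1]

    def reconstruct(self) -> np.ndarray:
        return self.coefficients @ self.components + self.mean


def pca_embed(sta_matrix: np.ndarray) -> PCAEmbedding:
    """L2-normalize STA rows and decompose them with PCA.

    Raises ``ValueError`` naming the first all-zero row, which cannot be
    normalized.
    """
    f = np.asarray(sta_matrix, dtype=float)
    if f.ndim != 2 or f.shape[0] < 4:
        raise ValueError("need an N x T matrix with N >= 4 rows")
    norms = np.linalg.norm(f, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"row {zero[0]} of the STA matrix is all zero")
    normalized = f / norms[:, None]
    pca = PCA(n_components=min(normalized.shape))
    coeffs = pca.fit_transform(normalized)
    components = pca.components_.copy()
    for k in range(components.shape[0]):
        if components[k, np.argmax(np.abs(components[k]))] < 0:
            components[k] = -components[k]
            coeffs[:, k] = -coeffs[:, k]
    return PCAEmbedding(
        components=components,
        coefficients=coeffs,
        variance_explained=pca.explained_variance_ratio_,
        mean=pca.mean_,
        normalized=normalized,
    )


def spherical_coords(coeffs3: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spherical angles of unit-normalized 3-component coefficients.

    Theta is the latitude ``arcsin(c3')`` (0 at the equator) and Phi the
    full-quadrant angle of ``(c1', c2')`` in degrees, in (-180, 180], so
    that STAs matching components one, two, and three map to (0, 0),
    (90, 0), and (theta = 90) respectively.
    """
    c = np.atleast_2d(np.asarray(coeffs3, dtype=float))
    if c.shape[1] != 3:
        raise ValueError("expected N x 3 coefficients")
    norms = np.linalg.norm(c, axis=1)
    if np.any(norms == 0):
        raise ValueError(f"row {int(np.flatnonzero(norms == 0)[0])} is all zero")
    c = c / norms[:, None]
    theta = np.degrees(np.arcsin(np.clip(c[:, 2], -1.0, 1.0)))
    phi = np.degrees(np.arctan2(c[:, 1], c[:, 0]))
    phi = np.where(phi <= -180.0, phi + 360.0, phi)
    return phi, theta


@dataclass
class PhiBinAverage:
    """Mean +/- SEM of non-normalized STAs inside one Phi bin."""

    center_deg: float
    n: int
    indices: np.ndarray
    mean: np.ndarray | None
    sem: np.ndarray | None


def population_average_by_phi(
    stas: np.ndarray,
    phi_deg: np.ndarray,
    center_deg: float,
    width_deg: float = 15.0,
) -> PhiBinAverage:
    """Average the *non-normalized* STAs whose Phi falls in the half-open
    bin ``[center - width/2, center + width/2)`` (angles wrap at 180)."""
    stas = np.asarray(stas, dtype=float)
    phi = np.asarray(phi_deg, dtype=float)
    delta = (phi - center_deg + 180.0) % 360.0 - 180.0
    mask = (delta >= -width_deg / 2.0) & (delta < width_deg / 2.0)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return PhiBinAverage(center_deg, 0, idx, None, None)
    sel = stas[idx]
    return PhiBinAverage(
        center_deg,
        int(idx.size),
        idx,
        sel.mean(axis=0),
        sel.std(axis=0, ddof=1) / np.sqrt(idx.size) if idx.size > 1 else np.zeros(sel.shape[1]),
    )


@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray
    silhouette: np.ndarray
    mean_silhouette_by_k: dict[int, float]


def kmeans_select_k(
    coeffs: np.ndarray,
    k_range: range = range(2, 11),
    seed: int = 0,
    restarts: int = 10,
) -> ClusterResult:
    """Cluster coefficient vectors with K-means, choosing K by silhouette.

    One K-means fit (best of ``restarts`` initializations) is run for
    each K in ``k_range``; the K maximizing the mean silhouette value
    ``s_i = (b_i - a_i) / max(a_i, b_i)`` is selected.
    """
    X = np.asarray(coeffs, dtype=float)
    if X.shape[0] <= max(k_range):
        raise ValueError("need more points than the largest K")
    if np.unique(X, axis=0).shape[0] < max(k_range) + 1:
        raise ValueError("too many duplicate points for the largest K")
    best = None
    means: dict[int, float] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
        sil = silhouette_samples(X, km.labels_)
        means[k] = float(sil.mean())
        if best is None or means[k] > means[best[0]]:
            best = (k, km.labels_, sil)
    return ClusterResult(best[0], best[1], best[2], means)
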