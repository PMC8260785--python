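"""Frame registration and QC, nuclei detection, and calibration fits.

Raster-scanned calcium movies drift when the animal moves.  Each frame
is registered to the per-pixel temporal median of the stack by locating
the peak of the Fourier-domain cross-correlation; a per-frame error,
``sqrt(1 - peak normalized cross-correlation)``, flags frames corrupted
by body movement under a robust median + 5*MAD rule.  Cell nuclei are
detected on time-averaged intensity images by morphological opening
followed by regional-maxima extraction with an area cap.  The module
also fits the exponential decay of the calcium indicator (used as the
AR(1) deconvolution kernel) and solves 3D affine point registration for
mapping cells onto a reference brain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage import morphology, measure
from skimage.registration import phase_cross_correlation

__all__ = [
    "AffineTransform",
    "ExpDecayFit",
    "register_frame",
    "register_stack",
    "flag_corrupted_frames",
    "detect_nuclei",
    "fit_affine",
    "fit_exponential_decay",
    "median_tau",
]

#: detections larger than this area (px^2) exceed typical nucleus size
#: and are discarded as false positives
MAX_NUCLEUS_AREA_PX2 = 144.0


def register_frame(
    frame: np.ndarray, reference: np.ndarray, upsample_factor: int = 1
) -> tuple[np.ndarray, float, np.ndarray]:
    """Estimate and apply the translation aligning ``frame`` to ``reference``.

    The shift is the argmax of the 2D cross-correlation computed in
    Fourier space (integer precision by default; set ``upsample_factor``
    for subpixel refinement).  The returned error is
    ``sqrt(1 - r)`` where ``r`` is the normalized cross-correlation of
    the registered frame with the reference; a zero-variance frame gets
    the maximal error 1.0.

    Returns ``(shift, error, registered_frame)``; translating the frame
    by ``shift`` aligns it to the reference.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise ValueError("frame and reference shapes must match")
    if np.ptp(frame) == 0 or np.ptp(reference) == 0:
        return np.zeros(2), 1.0, frame.copy()
    shift, _, _ = phase_cross_correlation(
        reference, frame, upsample_factor=upsample_factor, normalization=None
    )
    registered = ndimage.shift(frame, shift, order=1, mode="nearest")
    r = np.corrcoef(registered.ravel(), reference.ravel())[0, 1]
    error = float(np.sqrt(max(0.0, 1.0 - r)))
    return np.asarray(shift, dtype=float), error, registered


def register_stack(
    frames: np.ndarray, reference: np.ndarray | None = None, upsample_factor: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Register every frame of a stack to the per-pixel temporal median.

    Returns ``(shifts, errors, registered_frames)``.
    """
    frames = np.asarray(frames, dtype=float)
    if reference is None:
        reference = np.median(frames, axis=0)
    shifts = np.empty((frames.shape[0], 2))
    errors = np.empty(frames.shape[0])
    registered = np.empty_like(frames)
    for k, frame in enumerate(frames):
        shifts[k], errors[k], registered[k] = register_frame(
            frame, reference, upsample_factor=upsample_factor
        )
    return shifts, errors, registered


def flag_corrupted_frames(errors: np.ndarray) -> np.ndarray:
    """Flag frames whose registration error exceeds median + 5*MAD.

    The MAD is the raw median absolute deviation (no consistency
    factor); the inequality is strict, so an all-equal error vector
    flags nothing.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size < 2:
        raise ValueError("need at least two frames")
    med = np.median(errors)
    mad = np.median(np.abs(errors - med))
    return errors > med + 5.0 * mad


def detect_nuclei(
    time_avg_image: np.ndarray,
    opening_radius_px: int = 4,
    max_area_px2: float = MAX_NUCLEUS_AREA_PX2,
) -> list[tuple[tuple[float, float], float]]:
    """Detect nucleus centers on a time-averaged intensity image.

    The image is opened with a disk-shaped structuring element (radius 4
    px), regional maxima (connected equal-intensity plateaus exceeding
    all boundary neighbors) are extracted, and each plateau yields one
    detection at its center of mass.  Plateaus with area above
    ``max_area_px2`` — larger than typical nuclei — are discarded.

    Returns a list of ``((row, col), area_px2)`` pairs.
    """
    img = np.asarray(time_avg_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if img.size == 0 or np.ptp(img) == 0:
        return []
    opened = morphology.opening(img, morphology.disk(opening_radius_px))
    maxima = morphology.local_maxima(opened, connectivity=2, allow_borders=True)
    labels = measure.label(maxima, connectivity=2)
    out = []
    for region in measure.regionprops(labels):
        if region.area > max_area_px2:
            continue
        out.append(((float(region.centroid[0]), float(region.centroid[1])), float(region.area)))
    return out


@dataclass(frozen=True)
class AffineTransform:
    """3D affine map ``y = linear @ x + offset``."""

    linear: np.ndarray
    offset: np.ndarray
    residual_rms: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform a ``3 x k`` array of points."""
        return self.linear @ np.asarray(points, dtype=float) + self.offset[:, None]


def fit_affine(src_points: np.ndarray, dst_points: np.ndarray) -> AffineTransform:
    """Least-squares affine transform from source to destination points.

    ``src_points`` and ``dst_points`` are ``3 x k`` with ``k >= 4``
    non-coplanar correspondences; solves for the 3x3 matrix and
    translation minimizing the squared residual.
    """
    src = np.asarray(src_points, dtype=float)
    dst = np.asarray(dst_points, dtype=float)
    if src.shape != dst.shape or src.shape[0] != 3 or src.shape[1] < 4:
        raise ValueError("need matching 3 x k point sets with k >= 4")
    design = np.vstack([src, np.ones(src.shape[1])]).T  # k x 4
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("source points are rank-deficient (coplanar or collinear)")
    sol, *_ = np.linalg.lstsq(design, dst.T, rcond=None)  # 4 x 3
    linear = sol[:3].T
    offset = sol[3]
    resid = dst - (linear @ src + offset[:, None])
    rms = float(np.sqrt(np.mean(resid**2)))
    return AffineTransform(linear=linear, offset=offset, residual_rms=rms)


@dataclass(frozen=True)
class ExpDecayFit:
    """Result of fitting ``A * exp(-t / tau) + b`` to a post-saccadic STA."""

    amplitude: float
    tau_s: float
    offset: float
    r_squared: float

    @property
    def accepted(self) -> bool:
        return self.r_squared > 0.8


def fit_exponential_decay(
    sta_values: np.ndarray,
    time_grid: np.ndarray,
    baseline_window_s: tuple[float, float] = (-2.0, -1.0),
) -> ExpDecayFit:
    """Fit a decaying exponential to the post-saccade portion of an STA.

    The offset ``b`` is fixed to the mean of the pre-saccade baseline
    window (default 1-2 s before the saccade); ``A`` and ``tau`` minimize
    the squared error on the post-saccade samples subject to ``tau > 0``
    and ``A > b``.  The caller filters on ``r_squared > 0.8``.
    """
    y = np.asarray(sta_values, dtype=float)
    t = np.asarray(time_grid, dtype=float)
    if y.shape != t.shape:
        raise ValueError("sta_values and time_grid must align")
    base = (t >= baseline_window_s[0]) & (t <= baseline_window_s[1])
    if not base.any():
        raise ValueError("baseline window contains no samples")
    b = float(y[base].mean())
    post = t >= 0
    tp, yp = t[post], y[post]
    if tp.size < 5:
        raise ValueError("need at least 5 post-saccade samples")

    def loss(params):
        a, tau = params
        return np.sum((a * np.exp(-tp / tau) + b - yp) ** 2)

    a0 = max(float(yp[0] - b), 1e-6)
    res = optimize.minimize(
        loss,
        x0=[a0, 1.0],
        bounds=[(b + 1e-12, None), (1e-6, None)],
        method="L-BFGS-B",
    )
    a_fit, tau_fit = res.x
    pred = a_fit * np.exp(-tp / tau_fit) + b
    ss_res = float(np.sum((yp - pred) ** 2))
    ss_tot = float(np.sum((yp - yp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return ExpDecayFit(
        amplitude=float(a_fit),
        tau_s=float(tau_fit),
        offset=b,
        r_squared=max(0.0, min(1.0, r2)),
    )


def median_tau(fits: list[ExpDecayFit]) -> float:
    """Median decay constant over well-fit cells (r^2 > 0.8)."""
    taus = [f.tau_s for f in fits if f.accepted]
    if not taus:
        raise ValueError("no fits passed the r^2 > 0.8 criterion")
    return float(np.median(taus))
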