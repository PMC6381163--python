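"""Masked 2D texture features: GLCM/Haralick, GLRLM, GLGCM, NGLDM, Tamura
and gray-level-histogram families.

All matrices are built strictly from in-mask pixels (pairs, runs and
neighborhoods never cross the mask boundary).  Gray-level quantization is
range-relative equal-width binning over the in-mask intensities, with 16
levels for the co-occurrence matrix and 256 levels elsewhere.  Logarithms
are base 2 (entropies in bits) with the 0*log0 := 0 convention; statistics
that are undefined on degenerate input (zero variance) are defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "PreconditionError",
    "QuantizedImage",
    "CooccurrenceMatrix",
    "quantize_gray_levels",
    "compute_glcm",
    "haralick_features",
    "glrlm_features",
    "glgcm_features",
    "ngldm_features",
    "tamura_features",
    "histogram_features",
]

#: (row, col) step per angle, in degrees.  45 deg points up-right in image
#: coordinates (row decreases, col increases).
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


class PreconditionError(ValueError):
    """A feature family's input precondition is not met (e.g. mask too small)."""


@dataclass
class QuantizedImage:
    """Integer gray levels in {0..n_levels-1} under a binary mask."""

    levels: np.ndarray
    n_levels: int
    mask: np.ndarray
    bounds: tuple[float, float]


@dataclass
class CooccurrenceMatrix:
    matrix: np.ndarray          # G x G, sums to 1 when normalized
    normalized: bool
    angles: tuple[int, ...]
    distance: int


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def quantize_gray_levels(image: np.ndarray, mask: np.ndarray, n_levels: int
                         ) -> QuantizedImage:
    """Equal-width binning of in-mask intensities into ``n_levels`` levels.

    Bins span [min, max] of the in-mask values; a constant region maps to
    level 0 everywhere.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise PreconditionError("empty mask")
    image = np.asarray(image, dtype=np.float64)
    vals = image[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(image.shape, dtype=np.int64)
    # a range at floating-point noise level is a constant region
    if hi - lo > 1e-12 * max(1.0, abs(hi), abs(lo)):
        scaled = (image - lo) / (hi - lo) * n_levels
        levels = np.clip(np.floor(scaled), 0, n_levels - 1).astype(np.int64)
    levels[~mask] = 0
    return QuantizedImage(levels=levels, n_levels=n_levels, mask=mask, bounds=(lo, hi))


# --------------------------------------------------------------------------
# GLCM / Haralick
# --------------------------------------------------------------------------

def compute_glcm(q: QuantizedImage, distance: int = 1,
                 angles: tuple[int, ...] = (0, 45, 90, 135),
                 normalized: bool = True) -> CooccurrenceMatrix:
    """Symmetric gray-level co-occurrence matrix accumulated over angles.

    Both pixels of a pair must be in-mask; each unordered pair is counted in
    both directions (symmetric convention), counts from all angles are
    summed and then normalized to sum 1 (averaged-angle convention).
    """
    G = q.n_levels
    counts = np.zeros((G, G), dtype=np.float64)
    lv, m = q.levels, q.mask
    rows, cols = lv.shape
    for ang in angles:
        dr, dc = ANGLE_OFFSETS[ang]
        dr, dc = dr * distance, dc * distance
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        src = (slice(r0, r1), slice(c0, c1))
        dst = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
        valid = m[src] & m[dst]
        a = lv[src][valid]
        b = lv[dst][valid]
        if a.size:
            pair = np.bincount(a * G + b, minlength=G * G).reshape(G, G)
            counts += pair + pair.T
    total = counts.sum()
    if total == 0:
        raise PreconditionError("mask has no in-mask neighbor pairs")
    return CooccurrenceMatrix(matrix=counts / total if normalized else counts,
                              normalized=normalized, angles=tuple(angles),
                              distance=distance)


def haralick_features(P: CooccurrenceMatrix | np.ndarray) -> dict[str, float]:
    """Eight Haralick descriptors of a normalized co-occurrence matrix."""
    p = P.matrix if isinstance(P, CooccurrenceMatrix) else np.asarray(P, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("co-occurrence matrix must be normalized to sum 1")
    G = p.shape[0]
    i = np.arange(G)[:, None]
    j = np.arange(G)[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(np.arange(G) * px))
    mu_y = float(np.sum(np.arange(G) * py))
    sd_x = float(np.sqrt(np.sum((np.arange(G) - mu_x) ** 2 * px)))
    sd_y = float(np.sqrt(np.sum((np.arange(G) - mu_y) ** 2 * py)))
    if sd_x * sd_y > 0:
        correlation = float((np.sum(i * j * p) - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    p_sum = np.bincount((i + j).ravel(), weights=p.ravel(), minlength=2 * G - 1)
    k = np.arange(p_sum.size)
    return {
        "glcm_energy": float(np.sum(p**2)),
        "glcm_contrast": float(np.sum((i - j) ** 2 * p)),
        "glcm_correlation": correlation,
        "glcm_inverse_difference_moment": float(np.sum(p / (1.0 + (i - j) ** 2))),
        "glcm_entropy": _entropy_bits(p.ravel()),
        "glcm_variance": float(np.sum((np.arange(G) - mu_x) ** 2 * px)),
        "glcm_sum_average": float(np.sum(k * p_sum)),
        "glcm_sum_entropy": _entropy_bits(p_sum),
    }


# --------------------------------------------------------------------------
# GLRLM (Galloway run-length features)
# --------------------------------------------------------------------------

def _runs_along_lines(levels: np.ndarray, mask: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Run (level, length) pairs over the rows of a 2D array.

    A run is a maximal stretch of consecutive in-mask pixels with equal
    level; mask gaps break runs.
    """
    all_levels, all_lengths = [], []
    for lv_line, m_line in zip(levels, mask):
        m = m_line.astype(bool)
        if not m.any():
            continue
        prev_m = np.concatenate(([False], m[:-1]))
        same_prev = np.concatenate(([False], lv_line[1:] == lv_line[:-1]))
        starts = m & ~(prev_m & same_prev)
        run_id = np.cumsum(starts) - 1
        lengths = np.bincount(run_id[m])
        start_idx = np.flatnonzero(starts)
        all_levels.append(lv_line[start_idx])
        all_lengths.append(lengths)
    if not all_levels:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(all_levels), np.concatenate(all_lengths)


def run_length_matrix(q: QuantizedImage, angle: int) -> np.ndarray:
    """Run-length matrix R[g, r-1] for angle 0 (horizontal) or 90 (vertical)."""
    if angle == 0:
        lv, m = q.levels, q.mask
    elif angle == 90:
        lv, m = q.levels.T, q.mask.T
    else:
        raise ValueError("supported run angles: 0, 90")
    levels, lengths = _runs_along_lines(lv, m)
    max_len = int(lengths.max()) if lengths.size else 1
    R = np.zeros((q.n_levels, max_len), dtype=np.float64)
    np.add.at(R, (levels, lengths - 1), 1.0)
    return R


def _galloway(R: np.ndarray, n_pixels: int) -> dict[str, float]:
    n_runs = R.sum()
    r = np.arange(1, R.shape[1] + 1, dtype=np.float64)[None, :]
    return {
        "glrlm_sre": float(np.sum(R / r**2) / n_runs),
        "glrlm_lre": float(np.sum(R * r**2) / n_runs),
        "glrlm_gln": float(np.sum(R.sum(axis=1) ** 2) / n_runs),
        "glrlm_rln": float(np.sum(R.sum(axis=0) ** 2) / n_runs),
        "glrlm_rp": float(n_runs / n_pixels),
    }


def glrlm_features(q: QuantizedImage, angles: tuple[int, ...] = (0, 90)
                   ) -> dict[str, float]:
    """Galloway run-length features averaged over the given angles."""
    if not q.mask.any():
        raise PreconditionError("empty mask")
    n_pixels = int(q.mask.sum())
    per_angle = [_galloway(run_length_matrix(q, ang), n_pixels) for ang in angles]
    return {k: float(np.mean([d[k] for d in per_angle])) for k in per_angle[0]}


# --------------------------------------------------------------------------
# GLGCM (gray level - gradient magnitude co-occurrence)
# --------------------------------------------------------------------------

def sobel_magnitude(image: np.ndarray) -> np.ndarray:
    gx = ndimage.sobel(np.asarray(image, dtype=np.float64), axis=0, mode="nearest")
    gy = ndimage.sobel(np.asarray(image, dtype=np.float64), axis=1, mode="nearest")
    return np.hypot(gx, gy)


def gray_gradient_matrix(image: np.ndarray, mask: np.ndarray,
                         gray_levels: int = 256, gradient_levels: int = 16
                         ) -> np.ndarray:
    """Normalized joint histogram p(gray level, gradient level) over the mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 9:
        raise PreconditionError("mask too small for gradient features (need >= 9 px)")
    qg = quantize_gray_levels(image, mask, gray_levels)
    grad = sobel_magnitude(image)
    qs = quantize_gray_levels(grad, mask, gradient_levels)
    H = np.zeros((gray_levels, gradient_levels), dtype=np.float64)
    np.add.at(H, (qg.levels[mask], qs.levels[mask]), 1.0)
    return H / H.sum()


def glgcm_descriptors(p: np.ndarray) -> dict[str, float]:
    """The 15 classical gray-gradient descriptors of a normalized p(g, s).

    Level weights are 0-based for means/variances/correlation/inertia;
    emphasis terms weight the gradient level as (s+1)^2 so the smallest
    level contributes.
    """
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("joint histogram must be normalized")
    Gg, Gs = p.shape
    g = np.arange(Gg, dtype=np.float64)
    s = np.arange(Gs, dtype=np.float64)
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_g = float(np.sum(g * pg))
    mu_s = float(np.sum(s * ps))
    var_g = float(np.sum((g - mu_g) ** 2 * pg))
    var_s = float(np.sum((s - mu_s) ** 2 * ps))
    if var_g > 0 and var_s > 0:
        corr = float(np.sum((g[:, None] - mu_g) * (s[None, :] - mu_s) * p)
                     / np.sqrt(var_g * var_s))
    else:
        corr = 0.0
    gs_diff = g[:, None] - s[None, :]
    return {
        "glgcm_small_gradient_emphasis": float(np.sum(p / (s[None, :] + 1) ** 2)),
        "glgcm_large_gradient_emphasis": float(np.sum(p * (s[None, :] + 1) ** 2)),
        "glgcm_gray_nonuniformity": float(np.sum(pg**2)),
        "glgcm_gradient_nonuniformity": float(np.sum(ps**2)),
        "glgcm_energy": float(np.sum(p**2)),
        "glgcm_gray_mean": mu_g,
        "glgcm_gradient_mean": mu_s,
        "glgcm_gray_variance": var_g,
        "glgcm_gradient_variance": var_s,
        "glgcm_correlation": corr,
        "glgcm_gray_entropy": _entropy_bits(pg),
        "glgcm_gradient_entropy": _entropy_bits(ps),
        "glgcm_mixed_entropy": _entropy_bits(p.ravel()),
        "glgcm_inertia": float(np.sum(gs_diff**2 * p)),
        "glgcm_inverse_difference_moment": float(np.sum(p / (1.0 + gs_diff**2))),
    }


def glgcm_features(image: np.ndarray, mask: np.ndarray, gray_levels: int = 256,
                   gradient_levels: int = 16) -> dict[str, float]:
    return glgcm_descriptors(gray_gradient_matrix(image, mask, gray_levels,
                                                  gradient_levels))


# --------------------------------------------------------------------------
# NGLDM (neighboring gray-level dependence)
# --------------------------------------------------------------------------

def dependence_matrix(q: QuantizedImage, distance: int = 1, tolerance: int = 0
                      ) -> np.ndarray:
    """Q[g, k]: interior pixels of level g with k neighbors within tolerance.

    Only pixels whose full Chebyshev-``distance`` neighborhood lies in-mask
    are counted (interior convention), so k runs over 0..(2d+1)^2-1.
    """
    lv, m = q.levels, q.mask
    size = 2 * distance + 1
    interior = ndimage.binary_erosion(m, structure=np.ones((size, size), dtype=bool))
    if not interior.any():
        raise PreconditionError("no interior pixels for the dependence matrix")
    n_neigh = size * size - 1
    k = np.zeros(lv.shape, dtype=np.int64)
    for di in range(-distance, distance + 1):
        for dj in range(-distance, distance + 1):
            if di == 0 and dj == 0:
                continue
            shifted = np.roll(np.roll(lv, di, axis=0), dj, axis=1)
            k += (np.abs(shifted - lv) <= tolerance)
    Q = np.zeros((q.n_levels, n_neigh + 1), dtype=np.float64)
    np.add.at(Q, (lv[interior], k[interior]), 1.0)
    return Q


def ngldm_features(q: QuantizedImage, distance: int = 1, tolerance: int = 0
                   ) -> dict[str, float]:
    """Five dependence-matrix descriptors; the k=0 bucket uses weight 1 in
    the k^2 emphasis terms so it contributes rather than diverging."""
    Q = dependence_matrix(q, distance, tolerance)
    N = Q.sum()
    kk = np.arange(Q.shape[1], dtype=np.float64)
    kk_eff = np.maximum(kk, 1.0)[None, :]
    p = Q / N
    return {
        "ngldm_small_number_emphasis": float(np.sum(Q / kk_eff**2) / N),
        "ngldm_large_number_emphasis": float(np.sum(Q * kk_eff**2) / N),
        "ngldm_number_nonuniformity": float(np.sum(Q.sum(axis=1) ** 2) / N),
        "ngldm_second_moment": float(np.sum(Q**2) / N),
        "ngldm_entropy": _entropy_bits(p.ravel()),
    }


# --------------------------------------------------------------------------
# Tamura
# --------------------------------------------------------------------------

def _shifted_abs_diff(A: np.ndarray, shift: int, axis: int) -> np.ndarray:
    fwd = np.take(A, np.clip(np.arange(A.shape[axis]) + shift, 0, A.shape[axis] - 1),
                  axis=axis)
    bwd = np.take(A, np.clip(np.arange(A.shape[axis]) - shift, 0, A.shape[axis] - 1),
                  axis=axis)
    return np.abs(fwd - bwd)


def tamura_features(image: np.ndarray, mask: np.ndarray, max_scale: int = 4,
                    gradient_threshold: float = 1e-3, n_bins: int = 16
                    ) -> dict[str, float]:
    """Tamura coarseness, contrast and directionality over a masked region.

    coarseness: per pixel, the window size 2^k (k in 0..max_scale) whose
    horizontal/vertical average-difference response is largest (ties to the
    smallest k), averaged over in-mask pixels.
    contrast: sigma / kurtosis^(1/4) with kurtosis = mu4/sigma^4; 0 for a
    constant region.
    directionality: resultant length of the doubled-angle 16-bin histogram
    of Sobel orientations at in-mask pixels with gradient magnitude above
    ``gradient_threshold``; 0 when no pixel passes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise PreconditionError("empty mask")
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    if rows.sum() < 8 or cols.sum() < 8:
        raise PreconditionError("mask bounding box must be >= 8x8 for Tamura")
    image = np.asarray(image, dtype=np.float64)

    # -- coarseness
    best = np.zeros(image.shape)
    kstar = np.zeros(image.shape, dtype=np.int64)
    for k in range(max_scale + 1):
        win = 2**k
        A = ndimage.uniform_filter(image, size=win, mode="nearest")
        E = np.maximum(_shifted_abs_diff(A, win, axis=0),
                       _shifted_abs_diff(A, win, axis=1))
        better = E > best          # strict: ties keep the smaller k
        kstar[better] = k
        best = np.maximum(best, E)
    coarseness = float(np.mean(2.0 ** kstar[mask]))

    # -- contrast
    vals = image[mask]
    sd = vals.std()
    if sd > 1e-12 * max(1.0, abs(float(vals.mean()))):
        kurt = np.mean((vals - vals.mean()) ** 4) / sd**4
        contrast = float(sd / kurt**0.25)
    else:
        contrast = 0.0

    # -- directionality
    gx = ndimage.sobel(image, axis=0, mode="nearest")
    gy = ndimage.sobel(image, axis=1, mode="nearest")
    mag = np.hypot(gx, gy)
    sel = mask & (mag > gradient_threshold)
    if sel.any():
        theta = np.mod(np.arctan2(gy[sel], gx[sel]), np.pi)
        hist, edges = np.histogram(theta, bins=n_bins, range=(0.0, np.pi))
        p = hist / hist.sum()
        centers = (edges[:-1] + edges[1:]) / 2.0
        directionality = float(np.abs(np.sum(p * np.exp(2j * centers))))
    else:
        directionality = 0.0
    return {"tamura_coarseness": coarseness, "tamura_contrast": contrast,
            "tamura_directionality": directionality}


# --------------------------------------------------------------------------
# Gray-level histogram
# --------------------------------------------------------------------------

def histogram_features(image: np.ndarray, mask: np.ndarray, n_bins: int = 256
                       ) -> dict[str, float]:
    """First-order statistics of the in-mask intensities.

    Moments (mean, variance, skewness, excess kurtosis) are computed from
    the raw values; energy and entropy from the ``n_bins``-bin range-relative
    histogram.  Skewness and kurtosis are defined as 0 for a constant region.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise PreconditionError("empty mask")
    vals = np.asarray(image, dtype=np.float64)[mask]
    sd = vals.std()
    constant = sd <= 1e-12 * max(1.0, abs(float(vals.mean())))
    skew = float(stats.skew(vals)) if not constant else 0.0
    kurt = float(stats.kurtosis(vals)) if not constant else 0.0
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        hist, _ = np.histogram(vals, bins=n_bins, range=(lo, hi))
    else:
        hist = np.array([vals.size])
    p = hist / hist.sum()
    return {
        "hist_mean": float(vals.mean()),
        "hist_variance": float(vals.var()),
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_energy": float(np.sum(p**2)),
        "hist_entropy": _entropy_bits(p),
    }
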