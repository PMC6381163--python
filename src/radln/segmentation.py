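"""Seeded region growing and segmentation quality metrics.

The interactive four-step protocol (pick the slice with the enhancing mass,
draw a rectangular region of interest, click a seed, grow) is ported to a
non-interactive form: the ROI rectangle and seed voxel come from the cohort
table, the rectangle is propagated unchanged to every slice, and growing
accepts connected voxels whose intensity is within a tolerance ``T`` of a
reference value.

Quality metrics: Dice overlap against a gold-standard mask, and the
intraclass correlation coefficient ICC(2,1) (two-way random effects,
absolute agreement, single measurement) for per-feature stability across
repeated/perturbed segmentations.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imageio import Volume

logger = logging.getLogger(__name__)

__all__ = [
    "GrowParams",
    "StabilityReport",
    "propagate_roi",
    "grow_region",
    "dice_coefficient",
    "icc_absolute_agreement",
    "stability_filter",
]


@dataclass
class GrowParams:
    """Region-growing settings.

    threshold : intensity tolerance T >= 0 in normalized units.
    connectivity : 6 (faces) or 26 (faces+edges+corners) in 3D.
    criterion :
        * ``seed_window_median`` (default) — the reference intensity is the
          median over a small window centered on the seed, a deterministic
          robust stand-in for "the clicked voxel is representative of the
          bright core"; a single noisy/textured voxel is not a stable
          reference.
        * ``seed_value`` — the reference is the seed voxel's own intensity.
        * ``running_mean`` — candidates are compared against the running
          mean of the region grown so far, FIFO frontier in fixed axis
          order.
    roi : in-plane rectangle ``(row_start, row_stop, col_start, col_stop)``
        (half-open) applied to every slice, or None for the whole grid.
    """

    threshold: float = 0.25
    connectivity: int = 6
    criterion: str = "seed_window_median"
    reference_window: tuple[int, int, int] = (7, 7, 3)
    roi: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.criterion not in ("seed_value", "seed_window_median", "running_mean"):
            raise ValueError(
                "criterion must be seed_value, seed_window_median or running_mean")


@dataclass
class StabilityReport:
    icc: pd.Series                 # per-feature ICC(2,1) in [-1, 1]
    cutoff: float
    passing: list[str] = field(default_factory=list)


def propagate_roi(reference_rect: tuple[int, int, int, int], n_slices: int,
                  grid_shape: tuple[int, int] | None = None
                  ) -> list[tuple[int, int, int, int]]:
    """Copy the reference rectangle to every slice, clipped to bounds."""
    r0, r1, c0, c1 = reference_rect
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"empty ROI rectangle {reference_rect}")
    if grid_shape is not None:
        r0, r1 = max(0, r0), min(grid_shape[0], r1)
        c0, c1 = max(0, c0), min(grid_shape[1], c1)
        if r1 <= r0 or c1 <= c0:
            raise ValueError("ROI rectangle lies outside the grid")
    return [(r0, r1, c0, c1)] * n_slices


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def grow_region(vol: Volume | np.ndarray, seed_voxel: tuple[int, int, int],
                params: GrowParams | None = None) -> np.ndarray:
    """Grow a lesion mask from a seed voxel.

    Returns the maximal connected set reachable from the seed in which every
    accepted voxel satisfies ``|intensity - reference| <= T``; the seed is
    always included, so the result is never empty.
    """
    params = params or GrowParams()
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    if data.ndim != 3:
        raise ValueError("grow_region expects a 3D volume")
    seed = tuple(int(v) for v in seed_voxel)
    if any(s < 0 or s >= n for s, n in zip(seed, data.shape)):
        raise ValueError(f"seed voxel {seed} outside volume of shape {data.shape}")

    inroi = np.ones(data.shape, dtype=bool)
    if params.roi is not None:
        r0, r1, c0, c1 = params.roi
        if not (0 <= r0 < r1 <= data.shape[0] and 0 <= c0 < c1 <= data.shape[1]):
            raise ValueError(f"ROI {params.roi} outside image bounds")
        inroi[:] = False
        inroi[r0:r1, c0:c1, :] = True
        if not inroi[seed]:
            raise ValueError(f"seed voxel {seed} outside ROI {params.roi}")

    if params.criterion in ("seed_value", "seed_window_median"):
        if params.criterion == "seed_value":
            reference = float(data[seed])
        else:
            lo = [max(0, s - w // 2) for s, w in zip(seed, params.reference_window)]
            hi = [min(n, s + w // 2 + 1)
                  for s, n, w in zip(seed, data.shape, params.reference_window)]
            reference = float(np.median(
                data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]))
        candidates = (np.abs(data - reference) <= params.threshold) & inroi
        candidates[seed] = True
        labels, _ = ndimage.label(candidates, structure=_structure(params.connectivity))
        mask = (labels == labels[seed])
    else:
        mask = _grow_running_mean(data, seed, params, inroi)
    mask[seed] = True
    return mask.astype(np.uint8)


def _grow_running_mean(data: np.ndarray, seed: tuple[int, int, int],
                       params: GrowParams, inroi: np.ndarray) -> np.ndarray:
    """FIFO breadth-first growth against the running region mean.

    Neighbors are visited in fixed axis order (-r, +r, -c, +c, -s, +s, then
    the diagonal offsets for 26-connectivity), which pins down the result.
    """
    offsets = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    if params.connectivity == 26:
        offsets = [(di, dj, dk)
                   for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
                   if (di, dj, dk) != (0, 0, 0)]
    mask = np.zeros(data.shape, dtype=bool)
    mask[seed] = True
    total, count = float(data[seed]), 1
    frontier: deque = deque([seed])
    while frontier:
        i, j, k = frontier.popleft()
        for di, dj, dk in offsets:
            n = (i + di, j + dj, k + dk)
            if not (0 <= n[0] < data.shape[0] and 0 <= n[1] < data.shape[1]
                    and 0 <= n[2] < data.shape[2]):
                continue
            if mask[n] or not inroi[n]:
                continue
            if abs(float(data[n]) - total / count) <= params.threshold:
                mask[n] = True
                total += float(data[n])
                count += 1
                frontier.append(n)
    return mask


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        logger.info("dice_coefficient: both masks empty, returning 1.0")
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def icc_absolute_agreement(table: np.ndarray | pd.DataFrame) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``table`` is subjects x raters with no missing cells.  Computed from the
    two-way ANOVA mean squares::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR between-subject, MSC between-rater and MSE residual mean
    squares.  A table whose entries are all equal (zero variance everywhere)
    is defined as perfect agreement, 1.0.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing/non-finite cells in ICC table")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        if np.allclose(x, grand):
            logger.info("icc_absolute_agreement: constant table, defining ICC=1.0")
            return 1.0
        return 0.0
    return float((msr - mse) / denom)


def stability_filter(tables: list[pd.DataFrame], cutoff: float = 0.8) -> StabilityReport:
    """Per-feature ICC(2,1) across repeated segmentation variants.

    Each table is subjects x features from one segmentation variant (same
    subjects, same feature names); variants play the role of raters.
    Features with ICC strictly greater than ``cutoff`` pass.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 segmentation variants")
    ref = tables[0]
    for t in tables[1:]:
        if list(t.index) != list(ref.index) or list(t.columns) != list(ref.columns):
            raise ValueError("tables must share subject index and feature columns")
    icc = pd.Series(
        {feat: icc_absolute_agreement(
            np.column_stack([t[feat].to_numpy(dtype=float) for t in tables]))
         for feat in ref.columns}, dtype=float)
    passing = [f for f, v in icc.items() if v > cutoff]
    return StabilityReport(icc=icc, cutoff=cutoff, passing=passing)
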