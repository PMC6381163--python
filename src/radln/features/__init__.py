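"""The 58-feature radiomics vector for a segmented mass.

Families and canonical order: 16 morphology, 8 co-occurrence (Haralick),
5 run-length (Galloway), 15 gray-gradient co-occurrence, 5 neighboring
gray-level dependence, 3 Tamura, 6 gray-level histogram.  Texture families
use 16 gray levels for the co-occurrence matrix and 256 elsewhere.

Texture features are computed per axial slice intersecting the mask and
averaged across slices; morphology is computed on the maximum-area slice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..imageio import Volume
from .morphology import morphology_features
from .texture import (CooccurrenceMatrix, PreconditionError, QuantizedImage,
                      compute_glcm, glgcm_features, glrlm_features,
                      haralick_features, histogram_features, ngldm_features,
                      quantize_gray_levels, tamura_features)

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_REGISTRY",
    "FEATURE_NAMES",
    "FAMILIES",
    "TEXTURE_FAMILIES",
    "ExtractionConfig",
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
    "morphology_features",
    "select_slices",
    "extract_feature_vector",
    "extract_feature_matrix",
]

#: (name, family, formula sketch) — the frozen definition of every feature.
FEATURE_REGISTRY: list[tuple[str, str, str]] = [
    ("morph_area", "morphology", "pixel count of the region"),
    ("morph_perimeter", "morphology", "boundary polygon length"),
    ("morph_centroid_abscissa", "morphology", "centroid column / slice width"),
    ("morph_centroid_ordinate", "morphology", "centroid row / slice height"),
    ("morph_major_axis", "morphology", "major axis of the second-moment ellipse"),
    ("morph_minor_axis", "morphology", "minor axis of the second-moment ellipse"),
    ("morph_eccentricity", "morphology", "eccentricity of the second-moment ellipse"),
    ("morph_length_to_width_ratio", "morphology", "bounding-box long/short side"),
    ("morph_circularity", "morphology", "4*pi*A / P^2"),
    ("morph_compactness", "morphology", "P^2 / (4*pi*A)"),
    ("morph_solidity", "morphology", "A / convex hull area"),
    ("morph_extent", "morphology", "A / bounding-box area"),
    ("morph_equivalent_diameter", "morphology", "diameter of equal-area disk"),
    ("morph_convexity", "morphology", "convex hull perimeter / perimeter"),
    ("morph_radial_mean", "morphology", "mean normalized centroid-boundary distance"),
    ("morph_radial_sd", "morphology", "SD of normalized centroid-boundary distance"),
    ("glcm_energy", "glcm", "sum p^2"),
    ("glcm_contrast", "glcm", "sum (i-j)^2 p"),
    ("glcm_correlation", "glcm", "(sum ij p - mux*muy)/(sdx*sdy)"),
    ("glcm_inverse_difference_moment", "glcm", "sum p/(1+(i-j)^2)"),
    ("glcm_entropy", "glcm", "-sum p log2 p"),
    ("glcm_variance", "glcm", "sum (i-mu)^2 px"),
    ("glcm_sum_average", "glcm", "sum k p_{x+y}(k)"),
    ("glcm_sum_entropy", "glcm", "-sum p_{x+y} log2 p_{x+y}"),
    ("glrlm_sre", "glrlm", "short run emphasis"),
    ("glrlm_lre", "glrlm", "long run emphasis"),
    ("glrlm_gln", "glrlm", "gray-level nonuniformity"),
    ("glrlm_rln", "glrlm", "run-length nonuniformity"),
    ("glrlm_rp", "glrlm", "run percentage"),
    ("glgcm_small_gradient_emphasis", "glgcm", "sum p/(s+1)^2"),
    ("glgcm_large_gradient_emphasis", "glgcm", "sum p*(s+1)^2"),
    ("glgcm_gray_nonuniformity", "glgcm", "sum over g of marginal^2"),
    ("glgcm_gradient_nonuniformity", "glgcm", "sum over s of marginal^2"),
    ("glgcm_energy", "glgcm", "sum p^2"),
    ("glgcm_gray_mean", "glgcm", "mean gray level"),
    ("glgcm_gradient_mean", "glgcm", "mean gradient level"),
    ("glgcm_gray_variance", "glgcm", "variance of gray marginal"),
    ("glgcm_gradient_variance", "glgcm", "variance of gradient marginal"),
    ("glgcm_correlation", "glgcm", "gray-gradient correlation"),
    ("glgcm_gray_entropy", "glgcm", "-sum pg log2 pg"),
    ("glgcm_gradient_entropy", "glgcm", "-sum ps log2 ps"),
    ("glgcm_mixed_entropy", "glgcm", "-sum p log2 p"),
    ("glgcm_inertia", "glgcm", "sum (g-s)^2 p"),
    ("glgcm_inverse_difference_moment", "glgcm", "sum p/(1+(g-s)^2)"),
    ("ngldm_small_number_emphasis", "ngldm", "sum Q/k^2 / N"),
    ("ngldm_large_number_emphasis", "ngldm", "sum Q*k^2 / N"),
    ("ngldm_number_nonuniformity", "ngldm", "sum over g of (sum_k Q)^2 / N"),
    ("ngldm_second_moment", "ngldm", "sum Q^2 / N"),
    ("ngldm_entropy", "ngldm", "-sum (Q/N) log2 (Q/N)"),
    ("tamura_coarseness", "tamura", "mean optimal 2^k window size"),
    ("tamura_contrast", "tamura", "sigma / kurtosis^(1/4)"),
    ("tamura_directionality", "tamura", "orientation histogram concentration"),
    ("hist_mean", "histogram", "mean in-mask intensity"),
    ("hist_variance", "histogram", "variance of in-mask intensity"),
    ("hist_skewness", "histogram", "skewness (0 if constant)"),
    ("hist_kurtosis", "histogram", "excess kurtosis (0 if constant)"),
    ("hist_energy", "histogram", "sum p^2 over 256 bins"),
    ("hist_entropy", "histogram", "-sum p log2 p over 256 bins"),
]

FEATURE_NAMES: list[str] = [name for name, _, _ in FEATURE_REGISTRY]

FAMILIES: dict[str, list[str]] = {}
for _name, _family, _ in FEATURE_REGISTRY:
    FAMILIES.setdefault(_family, []).append(_name)

TEXTURE_FAMILIES = ["glcm", "glrlm", "glgcm", "ngldm", "tamura", "histogram"]


@dataclass
class ExtractionConfig:
    glcm_levels: int = 16
    other_levels: int = 256
    gradient_levels: int = 16
    glcm_distance: int = 1
    glcm_angles: tuple[int, ...] = (0, 45, 90, 135)
    glrlm_angles: tuple[int, ...] = (0, 90)
    ngldm_distance: int = 1
    ngldm_tolerance: int = 0
    aggregation: str = "mean"       # "mean" over slices, or "max_area" single slice


class FeatureExtractionError(RuntimeError):
    """No slice of the mask supports a required feature family."""


def select_slices(mask: np.ndarray) -> list[int]:
    """Ascending indices of axial slices intersecting the mask."""
    mask = np.asarray(mask)
    if mask.ndim != 3 or not mask.any():
        raise ValueError("expected a nonempty 3D mask")
    return [int(k) for k in np.flatnonzero(mask.any(axis=(0, 1)))]


def _texture_families_for_slice(image: np.ndarray, mask: np.ndarray,
                                cfg: ExtractionConfig) -> dict[str, dict[str, float]]:
    """Per-family feature dicts for one slice; families whose precondition
    fails on this slice are omitted."""
    out: dict[str, dict[str, float]] = {}
    fams = {
        "glcm": lambda: haralick_features(compute_glcm(
            quantize_gray_levels(image, mask, cfg.glcm_levels),
            distance=cfg.glcm_distance, angles=cfg.glcm_angles)),
        "glrlm": lambda: glrlm_features(
            quantize_gray_levels(image, mask, cfg.other_levels), angles=cfg.glrlm_angles),
        "glgcm": lambda: glgcm_features(image, mask, gray_levels=cfg.other_levels,
                                        gradient_levels=cfg.gradient_levels),
        "ngldm": lambda: ngldm_features(
            quantize_gray_levels(image, mask, cfg.other_levels),
            distance=cfg.ngldm_distance, tolerance=cfg.ngldm_tolerance),
        "tamura": lambda: tamura_features(image, mask),
        "histogram": lambda: histogram_features(image, mask),
    }
    for fam, fn in fams.items():
        try:
            out[fam] = fn()
        except PreconditionError:
            pass
    return out


def extract_feature_vector(vol: Volume | np.ndarray, mask: np.ndarray,
                           config: ExtractionConfig | None = None) -> pd.Series:
    """The 58-feature vector of one segmented mass.

    Texture families: computed on every mask-intersecting slice that meets
    the family's precondition, then averaged (a family valid on no slice is
    an error).  Morphology: computed on the maximum-area slice; if the
    3D-connected mask splits into several in-plane pieces there, the largest
    piece is used.
    """
    cfg = config or ExtractionConfig()
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if data.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    slices = select_slices(mask)

    areas = {k: int(mask[:, :, k].sum()) for k in slices}
    if cfg.aggregation == "max_area":
        slices = [max(areas, key=areas.get)]

    per_family: dict[str, list[dict[str, float]]] = {f: [] for f in TEXTURE_FAMILIES}
    for k in slices:
        for fam, vals in _texture_families_for_slice(
                data[:, :, k], mask[:, :, k], cfg).items():
            per_family[fam].append(vals)

    values: dict[str, float] = {}
    for fam in TEXTURE_FAMILIES:
        if not per_family[fam]:
            raise FeatureExtractionError(
                f"feature family '{fam}' computable on no slice of this mask")
        for name in FAMILIES[fam]:
            values[name] = float(np.mean([d[name] for d in per_family[fam]]))

    k_max = max(areas, key=areas.get)
    mslice = mask[:, :, k_max]
    from scipy import ndimage as _ndi
    labels, n_comp = _ndi.label(mslice)
    if n_comp > 1:
        sizes = _ndi.sum_labels(mslice, labels, index=np.arange(1, n_comp + 1))
        mslice = labels == (int(np.argmax(sizes)) + 1)
        logger.info("max-area slice has %d components; using the largest", n_comp)
    values.update(morphology_features(mslice))

    vec = pd.Series(values).reindex(FEATURE_NAMES)
    if vec.isna().any() or not np.all(np.isfinite(vec.to_numpy(dtype=float))):
        bad = list(vec.index[~np.isfinite(vec.to_numpy(dtype=float))])
        raise FeatureExtractionError(f"non-finite feature values: {bad}")
    return vec


def extract_feature_matrix(subjects, config: ExtractionConfig | None = None
                           ) -> pd.DataFrame:
    """Subjects x 58 table with ``subject_id`` index and ``label`` column.

    ``subjects`` yields ``(subject_id, label, volume, mask)`` tuples.
    Subjects whose extraction fails are excluded with a log message; the
    pipeline continues.
    """
    rows, ids, labels = [], [], []
    for sid, label, vol, mask in subjects:
        try:
            rows.append(extract_feature_vector(vol, mask, config))
        except (FeatureExtractionError, PreconditionError, ValueError) as exc:
            logger.warning("excluding subject %s: %s", sid, exc)
            continue
        ids.append(sid)
        labels.append(label)
    if not rows:
        raise FeatureExtractionError("no subject yielded a feature vector")
    out = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"))
    out.insert(0, "label", labels)
    return out
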