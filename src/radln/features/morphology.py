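"""2D shape descriptors of a segmented mass on a single slice."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

from .texture import PreconditionError

__all__ = ["morphology_features"]


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))


def morphology_features(mask_slice: np.ndarray) -> dict[str, float]:
    """Sixteen shape features of a single connected 2D region.

    Centroid coordinates are normalized by the slice dimensions (abscissa =
    column fraction, ordinate = row fraction); eccentricity is that of the
    ellipse with the same second central moments as the region;
    length-to-width ratio comes from the axis-aligned bounding box (longer
    over shorter side); radial statistics are centroid-to-boundary distances
    normalized by their maximum.
    """
    mask = np.asarray(mask_slice).astype(bool)
    if not mask.any():
        raise PreconditionError("empty mask slice")
    _, n_comp = ndimage.label(mask)
    if n_comp != 1:
        raise PreconditionError(f"expected a single connected region, got {n_comp}")

    region = measure.regionprops(mask.astype(np.uint8))[0]
    area = float(region.area)
    perimeter = float(region.perimeter)
    r_cen, c_cen = region.centroid
    rows, cols = mask.shape
    bb_r = region.bbox[2] - region.bbox[0]
    bb_c = region.bbox[3] - region.bbox[1]
    long_side, short_side = max(bb_r, bb_c), min(bb_r, bb_c)

    hull = region.image_convex.astype(np.uint8)
    hull_perimeter = float(measure.regionprops(hull)[0].perimeter)
    # thin regions can have zero 8-connected perimeter estimate; guard ratios
    circ = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0
    comp = perimeter**2 / (4.0 * np.pi * area) if area > 0 else 0.0
    convexity = hull_perimeter / perimeter if perimeter > 0 else 1.0

    bnd = np.argwhere(_boundary(mask))
    dists = np.hypot(bnd[:, 0] - r_cen, bnd[:, 1] - c_cen)
    dmax = dists.max()
    radial = dists / dmax if dmax > 0 else np.ones_like(dists)

    return {
        "morph_area": area,
        "morph_perimeter": perimeter,
        "morph_centroid_abscissa": c_cen / cols,
        "morph_centroid_ordinate": r_cen / rows,
        "morph_major_axis": float(region.axis_major_length),
        "morph_minor_axis": float(region.axis_minor_length),
        "morph_eccentricity": float(region.eccentricity),
        "morph_length_to_width_ratio": long_side / short_side,
        "morph_circularity": circ,
        "morph_compactness": comp,
        "morph_solidity": float(region.solidity),
        "morph_extent": float(region.extent),
        "morph_equivalent_diameter": float(region.equivalent_diameter_area),
        "morph_convexity": convexity,
        "morph_radial_mean": float(radial.mean()),
        "morph_radial_sd": float(radial.std()),
    }
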