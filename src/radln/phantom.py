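"""Synthetic lesion-phantom cohorts.

Generates labeled cohorts of contrast-enhanced-lesion volumes that stand in
for a two-class breast-MRI study population (52 metastasis / 63
non-metastasis lesions): one bright, optionally spiculated ellipsoidal mass
per subject, embedded in darker noisy background, with class-dependent
intensity, texture and shape effect sizes.

The texture model is a class-dependent Gaussian random field: white noise
convolved with an isotropic Gaussian kernel of width
``texture_correlation_length`` and rescaled to standard deviation
``texture_contrast``.  This gives analytic control over co-occurrence
contrast/correlation differences between the classes.  Spiculation is a
radial sinusoidal perturbation of the ellipsoid boundary.

Every output is a pure function of ``(params, seed)``; per-subject streams
are spawned deterministically from the master seed so cohorts reproduce
under parallel generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imageio import Volume, save_mask, save_volume

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomParams",
    "CohortRecord",
    "generate_lesion_mask",
    "synthesize_volume",
    "generate_subject",
    "draw_subject_params",
    "generate_cohort",
    "load_cohort",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = ["subject_id", "volume_path", "mask_path",
                  "seed_x", "seed_y", "seed_z", "label"]

#: Metastasis-class offsets applied on top of the base parameters.  Chosen as
#: the "strong effect" study condition: each offset is about 1-1.5
#: subject-level standard deviations, so intensity, texture and shape each
#: carry real but imperfect signal and their combination separates the
#: classes better than any one family alone.
DEFAULT_CLASS_EFFECT = {
    "lesion_mean_intensity": 0.08,
    "texture_contrast": 0.05,
    "texture_correlation_length": 0.8,
    "lesion_radius": 0.6,
    "spiculation_amplitude": 0.08,
}


@dataclass
class PhantomParams:
    """Generator settings; defaults are the desk-scale study conditions."""

    grid_shape: tuple[int, int, int] = (64, 64, 16)
    lesion_radius_range: tuple[float, float] = (4.0, 7.0)
    z_radius_fraction: float = 0.5          # lesion semi-axis along slices / in-plane radius
    spiculation_amplitude: float = 0.12     # fraction of radius, in [0, 1]
    spiculation_lobes: int = 6              # angular frequency of the boundary perturbation
    lesion_mean_intensity: float = 0.70
    background_mean_intensity: float = 0.30
    texture_correlation_length: float = 1.2  # voxels
    texture_contrast: float = 0.10          # SD of the lesion texture field
    noise_sd: float = 0.05                  # acquisition noise, normalized units
    # between-subject jitter: no two lesions of a class are alike, so no
    # single generator axis separates the classes perfectly
    subject_intensity_sd: float = 0.06
    subject_spiculation_sd: float = 0.06
    subject_texture_contrast_sd: float = 0.03
    subject_correlation_length_sd: float = 0.3
    class_effect: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_EFFECT))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lesion_mean_intensity", "background_mean_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.spiculation_amplitude <= 1.0:
            raise ValueError("spiculation_amplitude must be in [0, 1]")
        lo, hi = self.lesion_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("lesion_radius_range must be positive and ordered")
        max_extent = hi * (1.0 + self.spiculation_amplitude
                           + self.class_effect.get("spiculation_amplitude", 0.0)) \
            + self.class_effect.get("lesion_radius", 0.0)
        if 2 * max_extent + 2 > min(self.grid_shape[0], self.grid_shape[1]):
            raise ValueError(
                f"lesion radius {hi} (+spiculation/effects) does not fit in "
                f"grid {self.grid_shape}")

    def for_class(self, label: str) -> dict[str, float]:
        """Effective per-class parameter values (offsets applied for metastasis)."""
        eff = dict(self.class_effect) if label == "metastasis" else {}
        return {
            "lesion_mean_intensity": self.lesion_mean_intensity
            + eff.get("lesion_mean_intensity", 0.0),
            "texture_contrast": self.texture_contrast + eff.get("texture_contrast", 0.0),
            "texture_correlation_length": self.texture_correlation_length
            + eff.get("texture_correlation_length", 0.0),
            "radius_offset": eff.get("lesion_radius", 0.0),
            "spiculation_amplitude": min(1.0, self.spiculation_amplitude
                                         + eff.get("spiculation_amplitude", 0.0)),
        }


def draw_subject_params(params: PhantomParams, label: str,
                        rng: np.random.Generator) -> dict[str, float]:
    """Per-subject effective parameters: class values plus subject jitter."""
    eff = params.for_class(label)
    eff["lesion_mean_intensity"] = float(np.clip(
        eff["lesion_mean_intensity"]
        + rng.normal(0.0, params.subject_intensity_sd), 0.0, 1.0))
    eff["spiculation_amplitude"] = float(np.clip(
        eff["spiculation_amplitude"]
        + rng.normal(0.0, params.subject_spiculation_sd), 0.0, 1.0))
    eff["texture_contrast"] = float(max(0.0,
        eff["texture_contrast"]
        + rng.normal(0.0, params.subject_texture_contrast_sd)))
    eff["texture_correlation_length"] = float(max(0.4,
        eff["texture_correlation_length"]
        + rng.normal(0.0, params.subject_correlation_length_sd)))
    return eff


@dataclass
class CohortRecord:
    subject_id: str
    volume_path: str
    mask_path: str
    seed_voxel: tuple[int, int, int]
    label: str

    def __post_init__(self) -> None:
        if self.label not in ("metastasis", "nonmetastasis"):
            raise ValueError(f"label must be metastasis|nonmetastasis, got {self.label}")


def generate_lesion_mask(params: PhantomParams, rng: np.random.Generator,
                         radius: float | None = None,
                         spiculation: float | None = None,
                         center: tuple[float, float, float] | None = None) -> np.ndarray:
    """Draw a single spiculated-ellipsoid lesion mask on the phantom grid.

    The boundary is ``r(theta, phi) <= R * (1 + a*sin(m*theta)*sin(phi))`` in
    ellipsoid-normalized radial coordinates: ``m`` angular lobes, strongest
    in the equatorial (axial) plane and fading toward the poles; ``a = 0``
    yields a discrete ellipsoid.  Returns a uint8 mask with a single
    26-connected component containing the grid voxel nearest the lesion
    center.
    """
    shape = params.grid_shape
    if radius is None:
        radius = rng.uniform(*params.lesion_radius_range)
    if spiculation is None:
        spiculation = params.spiculation_amplitude
    if center is None:
        margin = radius * (1 + spiculation) + 2
        center = (
            rng.uniform(margin, shape[0] - margin),
            rng.uniform(margin, shape[1] - margin),
            shape[2] / 2.0 + rng.uniform(-1.0, 1.0),
        )
    rz = max(1.5, radius * params.z_radius_fraction)

    ii, jj, kk = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             np.arange(shape[2]), indexing="ij")
    di = (ii - center[0]) / radius
    dj = (jj - center[1]) / radius
    dk = (kk - center[2]) / rz
    rho = np.sqrt(di**2 + dj**2 + dk**2)
    theta = np.arctan2(dj, di)
    phi = np.arctan2(np.hypot(di, dj), dk)
    m = params.spiculation_lobes
    boundary = 1.0 + spiculation * np.sin(m * theta) * np.sin(phi)
    mask = (rho <= boundary).astype(np.uint8)

    # keep only the component containing the center voxel (spikes cannot detach)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    cvox = tuple(int(round(c)) for c in center)
    lab = labels[cvox]
    if lab == 0:  # center fell between voxels of a thin mask; use largest component
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        lab = int(np.argmax(sizes)) + 1
    mask = (labels == lab).astype(np.uint8)
    if mask.sum() == 0:
        raise ValueError("degenerate lesion: empty mask")
    return mask


def _gaussian_random_field(shape, correlation_length: float, contrast: float,
                           rng: np.random.Generator,
                           mask: np.ndarray | None = None) -> np.ndarray:
    """White noise smoothed to the given correlation length.

    The field is centered and scaled over ``mask`` (mean 0, SD = contrast
    in-mask), so texture modulates structure around the lesion's enhancement
    level without shifting its mean: with only a few correlation blobs
    inside a small lesion, an uncentered field would move the regional mean
    by a large random offset and confound the intensity axis.
    """
    white = rng.standard_normal(shape)
    if correlation_length > 0:
        fieldv = ndimage.gaussian_filter(white, sigma=correlation_length, mode="wrap")
    else:
        fieldv = white
    region = fieldv[mask > 0] if mask is not None else fieldv
    sd = region.std()
    if sd > 0 and contrast > 0:
        fieldv = (fieldv - region.mean()) * (contrast / sd)
    else:
        fieldv = np.zeros(shape)
    return fieldv


def synthesize_volume(mask: np.ndarray, params: PhantomParams, class_label: str,
                      rng: np.random.Generator,
                      eff: dict[str, float] | None = None) -> Volume:
    """Fill a lesion mask with class-textured signal over noisy background.

    Lesion voxels = lesion mean + Gaussian-random-field texture + noise;
    background voxels = background mean + noise; everything clipped to [0, 1].
    ``eff`` carries per-subject effective parameters (see
    :func:`draw_subject_params`); without it the class-level values are used
    with subject jitter applied to the lesion mean only.  A warning is
    logged if clipping touches more than 20% of lesion voxels (effect sizes
    would be distorted).
    """
    shape = mask.shape
    if eff is None:
        eff = params.for_class(class_label)
        eff["lesion_mean_intensity"] = eff["lesion_mean_intensity"] \
            + rng.normal(0.0, params.subject_intensity_sd)
    texture = _gaussian_random_field(shape, eff["texture_correlation_length"],
                                     eff["texture_contrast"], rng, mask=mask)
    lesion_mean = eff["lesion_mean_intensity"]
    noise = rng.normal(0.0, params.noise_sd, shape) if params.noise_sd > 0 else 0.0
    data = np.where(mask > 0, lesion_mean + texture,
                    params.background_mean_intensity) + noise
    inmask = data[mask > 0]
    clipped_frac = np.mean((inmask < 0) | (inmask > 1)) if inmask.size else 0.0
    if clipped_frac > 0.20:
        logger.warning("synthesize_volume: %.0f%% of lesion voxels clipped; "
                       "effect sizes distorted", 100 * clipped_frac)
    return Volume(data=np.clip(data, 0.0, 1.0).astype(np.float32))


def _subject_rng(master_seed: int, index: int) -> np.random.Generator:
    """Deterministic per-subject stream spawned from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index,)))


def _centroid_voxel(mask: np.ndarray) -> tuple[int, int, int]:
    com = ndimage.center_of_mass(mask)
    vox = tuple(int(round(c)) for c in com)
    if mask[vox]:
        return vox
    # centroid fell outside (strongly spiculated shapes): nearest in-mask voxel
    idx = np.argwhere(mask > 0)
    d = np.sum((idx - np.array(vox)) ** 2, axis=1)
    return tuple(int(v) for v in idx[np.argmin(d)])


def generate_subject(params: PhantomParams, index: int, label: str
                     ) -> tuple[np.ndarray, Volume, tuple[int, int, int]]:
    """In-memory single subject: (ground-truth mask, volume, centroid seed voxel).

    Subject ``index`` draws from its own sub-stream of ``params.seed``, so
    this is exactly what :func:`generate_cohort` writes to disk for that
    subject.
    """
    rng = _subject_rng(params.seed, index)
    eff = draw_subject_params(params, label, rng)
    radius = rng.uniform(*params.lesion_radius_range) + eff["radius_offset"]
    mask = generate_lesion_mask(params, rng, radius=radius,
                                spiculation=eff["spiculation_amplitude"])
    vol = synthesize_volume(mask, params, label, rng, eff=eff)
    return mask, vol, _centroid_voxel(mask)


def generate_cohort(n_metastasis: int, n_nonmetastasis: int, params: PhantomParams,
                    out_dir) -> list[CohortRecord]:
    """Generate a labeled cohort; writes NIfTI volumes/masks and a cohort CSV.

    Subjects are ordered metastasis first, each drawn from its own
    deterministic sub-stream of ``params.seed``.  The region-growing seed
    voxel is placed at each ground-truth mask's centroid.
    """
    if n_metastasis < 1 or n_nonmetastasis < 1:
        raise ValueError("both class counts must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create cohort directory {out_dir}: {exc}") from exc

    labels = ["metastasis"] * n_metastasis + ["nonmetastasis"] * n_nonmetastasis
    records: list[CohortRecord] = []
    for idx, label in enumerate(labels):
        mask, vol, seed_voxel = generate_subject(params, idx, label)
        sid = f"S{idx:04d}"
        vpath = out_dir / f"{sid}_vol.nii.gz"
        mpath = out_dir / f"{sid}_mask.nii.gz"
        try:
            save_volume(vpath, vol)
            save_mask(mpath, mask)
        except OSError as exc:
            raise IOError(f"cannot write phantom files under {out_dir}: {exc}") from exc
        records.append(CohortRecord(subject_id=sid, volume_path=str(vpath),
                                    mask_path=str(mpath), seed_voxel=seed_voxel,
                                    label=label))

    table = pd.DataFrame(
        [{"subject_id": r.subject_id, "volume_path": r.volume_path,
          "mask_path": r.mask_path, "seed_x": r.seed_voxel[0],
          "seed_y": r.seed_voxel[1], "seed_z": r.seed_voxel[2],
          "label": r.label} for r in records],
        columns=COHORT_COLUMNS)
    table.to_csv(out_dir / "cohort.csv", index=False)
    return records


def load_cohort(csv_path) -> list[CohortRecord]:
    """Read a cohort CSV back into records."""
    table = pd.read_csv(csv_path)
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return [CohortRecord(subject_id=str(row.subject_id), volume_path=row.volume_path,
                         mask_path=row.mask_path,
                         seed_voxel=(int(row.seed_x), int(row.seed_y), int(row.seed_z)),
                         label=row.label)
            for row in table.itertuples()]
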