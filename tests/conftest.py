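import logging

import numpy as np
import pytest

from radln import phantom

logging.getLogger("radln").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_params():
    return phantom.PhantomParams(seed=7)


@pytest.fixture(scope="session")
def phantom_subject(default_params):
    """One metastasis-class phantom: (ground-truth mask, volume, seed voxel)."""
    return phantom.generate_subject(default_params, 0, "metastasis")


def random_masked_image(seed, shape=(8, 8), n_levels=4, p_mask=0.8):
    """Random quantized image + random mask for brute-force comparisons."""
    g = np.random.default_rng(seed)
    levels = g.integers(0, n_levels, size=shape)
    mask = g.random(shape) < p_mask
    if not mask.any():
        mask[0, 0] = True
    return levels, mask


def cohort_feature_table(seed, n_met, n_nonmet, use_truth_masks=True, **param_kw):
    """Feature table for an in-memory phantom cohort.

    With ``use_truth_masks`` False, masks come from region growing at the
    default settings (the full pipeline path).
    """
    from radln import features, segmentation

    params = phantom.PhantomParams(seed=seed, **param_kw)
    labels = ["metastasis"] * n_met + ["nonmetastasis"] * n_nonmet

    def subjects():
        for i, lab in enumerate(labels):
            mask, vol, seed_vox = phantom.generate_subject(params, i, lab)
            if not use_truth_masks:
                mask = segmentation.grow_region(vol, seed_vox, segmentation.GrowParams())
            yield f"S{i:04d}", lab, vol, mask

    table = features.extract_feature_matrix(subjects())
    X = table.drop(columns=["label"])
    y = (table["label"] == "metastasis").astype(int).to_numpy()
    return X, y
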