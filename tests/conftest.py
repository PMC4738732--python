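"""Shared fixtures: small synthetic datasets with cached feature stacks.

Feature extraction dominates test runtime, so the session-scoped dataset is
extracted once and shared by the model, prior, saliency and CV tests.
"""

import numpy as np
import pytest

import salmedex as sx


SMALL_SHAPE = (128, 168)  # enough room for 3 pyramid scales and the margin


def make_small_config(**overrides):
    defaults = dict(
        image_height=SMALL_SHAPE[0], image_width=SMALL_SHAPE[1],
        fovea_radius=16.0, center_bias_sigma=18.0, n_lesions=3,
        fixations_per_observer=150, n_observers=6, seed=0,
    )
    defaults.update(overrides)
    return sx.SynthConfig(**defaults)


@pytest.fixture(scope="session")
def small_config():
    return make_small_config()


@pytest.fixture(scope="session")
def small_image(small_config):
    return sx.synth_fundus(small_config)


@pytest.fixture(scope="session")
def small_dataset():
    """10 small images with ground truths and cached feature stacks."""
    pairs = sx.synth_dataset(10, make_small_config(), seed=11)
    images = [img for img, _ in pairs]
    gts = [sx.ground_truth_map(seqs, img.shape) for img, seqs in pairs]
    stacks = {img.image_id: sx.extract_features(img) for img in images}
    return images, gts, stacks


@pytest.fixture(scope="session")
def trained_small_model(small_dataset):
    """SVM + prior trained on the first 7 images of the small dataset."""
    images, gts, stacks = small_dataset
    train_ids = [img.image_id for img in images[:7]]
    gt_by_id = {img.image_id: gt for img, gt in zip(images, gts)}
    sets = [sx.select_samples(stacks[iid], gt_by_id[iid], seed=j, image_id=iid)
            for j, iid in enumerate(train_ids)]
    model = sx.train_fp(sx.pool_samples(sets), seed=0)
    prior = sx.position_prior([gt_by_id[iid] for iid in train_ids])
    return model, prior
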