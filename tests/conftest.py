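"""Shared fixtures.

The expensive artifacts (the default synthetic B-scan dataset, a classifier
trained on its training split, a 500-nucleus slide) are session-scoped so
unit and acceptance tests reuse one computation.
"""

import numpy as np
import pytest

from fioct import synthetic_data as sd
from fioct import tumor_classifier as tc


@pytest.fixture(scope="session")
def two_class_dataset() -> sd.LabeledBScanSet:
    """Default study-scale dataset: 36 patients, 6 B-scans each, 2 classes."""
    return sd.simulate_bscan_dataset(n_patients=36, bscans_per_sample=6, seed=0)


@pytest.fixture(scope="session")
def trained_two_class(two_class_dataset) -> tc.TrainedClassifier:
    """CNN fitted on the dataset's training split at the evaluation config."""
    train, _ = two_class_dataset.train_test()
    return tc.train_model(train, tc.evaluation_config(seed=0))


@pytest.fixture(scope="session")
def he_slide_500():
    """1024x1024 synthetic H&E slide with 500 non-overlapping nuclei."""
    spec = sd.HESlideSpec(shape=(1024, 1024), n_nuclei=500, seed=5)
    rgb, truth = sd.simulate_he_image(spec)
    return spec, rgb, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
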