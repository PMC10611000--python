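import numpy as np
import pandas as pd
import pytest

from feelpix.dataset_builder import build_samples
from feelpix.landmark_processing import extract_features
from feelpix.stimulus_selection import RatingsTable
from feelpix.synthetic_data import GeneratorConfig, generate_landmarks, generate_ratings


def make_ratings_df(rows):
    """Build a ratings DataFrame from dicts, filling unspecified fields."""
    records = []
    for i, row in enumerate(rows):
        rec = {
            "image_id": f"im{i:03d}",
            "category": "objects",
            "valence_mean": 5.0,
            "arousal_mean": 5.0,
            "labels": frozenset(),
            "int_anger": 1.0, "int_disgust": 1.0, "int_fear": 1.0,
            "int_happy": 1.0, "int_sad": 1.0, "int_surprise": 1.0,
        }
        rec.update(row)
        records.append(rec)
    return pd.DataFrame(records)


@pytest.fixture(scope="session")
def ratings_table():
    """Generator-produced 700-image norms table."""
    return generate_ratings(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def landmark_dataset():
    """Small separable landmark dataset (6 subjects x 35 images)."""
    config = GeneratorConfig(seed=5, n_subjects=6, noise_sd=0.1)
    return generate_landmarks(config)


@pytest.fixture(scope="session")
def feelpix_samples(landmark_dataset):
    """Labelled samples built from the small landmark dataset."""
    ds = landmark_dataset
    X = np.stack([extract_features(f) for f in ds.frames])
    return build_samples(X, ds.selections, sample_ids=ds.sample_ids,
                         subjects=ds.subjects)
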