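"""Shared fixtures: a small synthetic dataset on disk and a nearest-centroid
oracle classifier kept independent of the package's network code."""

from __future__ import annotations

import numpy as np
import pytest

from imgclean import data, generate_synthetic_dataset
from imgclean.manifest import DatasetManifest


class NearestCentroid:
    """Raw-pixel nearest-centroid classifier — the independent oracle used to
    cross-check separability and flagging behaviour."""

    def __init__(self, centroids: np.ndarray):
        self.centroids = centroids  # (2, D)

    @classmethod
    def fit(cls, x: np.ndarray, y: np.ndarray) -> "NearestCentroid":
        xf = x.reshape(len(x), -1)
        return cls(np.stack([xf[y == c].mean(axis=0) for c in (0, 1)]))

    def predict(self, x: np.ndarray) -> np.ndarray:
        xf = x.reshape(len(x), -1)
        d = np.linalg.norm(xf[:, None, :] - self.centroids[None], axis=2)
        return d.argmin(axis=1)


def centroid_on_true_labels(manifest: DatasetManifest, image_size: int = 32
                            ) -> NearestCentroid:
    """Fit the oracle on ground-truth labels (records with a true_label)."""
    images, _ = data.load_images(manifest, image_size)
    truth = manifest.subset(r.image_id for r in manifest
                            if r.true_label is not None)
    x = np.stack([images[r.image_id] for r in truth])
    y = np.array([r.true_label for r in truth])
    return NearestCentroid.fit(x, y)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory) -> DatasetManifest:
    """40 images (20 per class, 6 groups, 32x32), all clean, on disk."""
    out = tmp_path_factory.mktemp("tiny")
    return generate_synthetic_dataset(20, 6, 32, seed=11, out_dir=out)


@pytest.fixture(scope="session")
def tiny_images(tiny_dataset):
    images, errors = data.load_images(tiny_dataset, 32)
    assert not errors
    return images
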