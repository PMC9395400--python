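"""Image loading for training and inference.

Images are decoded with Pillow, converted to RGB, resized with bilinear
interpolation, scaled to [0, 1] and normalised to [-1, 1] (mean 0.5, std
0.5 per channel), matching how the synthetic generator writes them.  No
augmentation is applied anywhere in the pipeline.

Unreadable files are not fatal: :func:`load_images` reports them separately
so the cleaner can treat them as background-noise candidates.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from .manifest import DatasetManifest


def load_image(path: str, image_size: int) -> np.ndarray:
    """One image -> float32 array of shape (3, image_size, image_size) in [-1, 1]."""
    with Image.open(path) as im:
        im = im.convert("RGB")
        if im.size != (image_size, image_size):
            im = im.resize((image_size, image_size), Image.BILINEAR)
        arr = np.asarray(im, dtype=np.float32) / 255.0
    return ((arr - 0.5) / 0.5).transpose(2, 0, 1)


def load_images(manifest: DatasetManifest, image_size: int
                ) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Load every image in the manifest.

    Returns ``(images, errors)``: id -> array for readable files, and
    id -> error message for unreadable ones.
    """
    images: dict[str, np.ndarray] = {}
    errors: dict[str, str] = {}
    for rec in manifest:
        try:
            images[rec.image_id] = load_image(rec.filepath, image_size)
        except (OSError, ValueError) as exc:
            errors[rec.image_id] = str(exc)
    return images, errors


def stack(manifest: DatasetManifest, images: dict[str, np.ndarray]
          ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack the readable images of a manifest into (X, y, ids) arrays,
    preserving manifest order and skipping ids absent from ``images``."""
    ids = [r.image_id for r in manifest if r.image_id in images]
    labels = {r.image_id: r.observed_label for r in manifest}
    x = np.stack([images[i] for i in ids]).astype(np.float32)
    y = np.array([labels[i] for i in ids], dtype=np.int64)
    return x, y, ids
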