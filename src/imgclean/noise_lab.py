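"""Synthetic two-class image datasets with controlled noise injection.

The generator emulates the statistical structure of a two-class endoscopy
dataset without any patient data:

* two visually separable parametric classes — an oriented-stripe texture
  ("stripes", class 0) and a Gaussian-blob texture ("blobs", class 1) with
  distinct colour casts;
* a patient-like grouping: each image belongs to one group, groups belong to
  one class, and images within a group share appearance parameters
  (orientation, brightness, tint jitter), emulating the within-patient
  correlation that motivates group-disjoint splitting;
* noise injection operators for the three noise families: intra-class label
  flips, out-of-class distractors relabeled into the two classes, and
  background degradation (heavy blur, occlusion, or a shrunken target).

All operators are deterministic given their seed, never alter the ids of
pre-existing records, and preserve ground truth (a flipped record keeps its
``true_label``), so a cleaning run can always be scored afterwards.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .manifest import DatasetManifest, ImageRecord

CLASS_NAMES = ("stripes", "blobs")
DISTRACTOR_NAME = "checker"


@dataclass(frozen=True)
class NoiseSpec:
    """A complete noise condition: per-class flip count, distractor count per
    class, fraction of images degraded, and the seed controlling all three."""

    intra_per_class: int = 0
    extra_count: int = 0
    background_fraction: float = 0.0
    seed: int = 0


def _coords(size: int) -> tuple[np.ndarray, np.ndarray]:
    ax = np.linspace(-1.0, 1.0, size)
    return np.meshgrid(ax, ax, indexing="ij")


def _stripes_image(size: int, angle: float, freq: float, phase: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Oriented sinusoidal grating, warm colour cast. Values in [0,1], HWC."""
    yy, xx = _coords(size)
    t = xx * np.cos(angle) + yy * np.sin(angle)
    g = 0.5 + 0.38 * np.sin(2.0 * np.pi * freq * t + phase)
    img = np.stack([g * 0.95 + 0.05, g * 0.55 + 0.10, g * 0.45 + 0.05], axis=-1)
    img += rng.normal(0.0, 0.04, img.shape)
    return np.clip(img, 0.0, 1.0)


def _blobs_image(size: int, n_blobs: int, width: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Sum of Gaussian bumps, cool colour cast. Values in [0,1], HWC."""
    yy, xx = _coords(size)
    g = np.zeros((size, size))
    for _ in range(n_blobs):
        cy, cx = rng.uniform(-0.9, 0.9, 2)
        g += np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * width ** 2))
    g = g / max(g.max(), 1e-9)
    img = np.stack([g * 0.35 + 0.05, g * 0.65 + 0.15, g * 0.95 + 0.05], axis=-1)
    img += rng.normal(0.0, 0.04, img.shape)
    return np.clip(img, 0.0, 1.0)


def _checker_image(size: int, cells: int, rng: np.random.Generator
                   ) -> np.ndarray:
    """Checkerboard distractor, green cast — visually unlike either class."""
    idx = np.arange(size) * cells // size
    board = (idx[:, None] + idx[None, :]) % 2
    g = board * 0.7 + 0.15
    img = np.stack([g * 0.45, g * 0.95, g * 0.35], axis=-1)
    img += rng.normal(0.0, 0.04, img.shape)
    return np.clip(img, 0.0, 1.0)


def _save(img: np.ndarray, path: str) -> None:
    Image.fromarray((img * 255.0 + 0.5).astype(np.uint8)).save(path)


def generate_synthetic_dataset(n_per_class: int, n_groups: int,
                               image_size: int, seed: int,
                               out_dir: str | os.PathLike
                               ) -> DatasetManifest:
    """Write ``2 * n_per_class`` PNG images of the two parametric classes.

    Groups are split evenly between the classes (a patient has one disease);
    each group carries appearance jitter shared by its images.  All records
    are tagged ``clean`` with ``true_label == observed_label``.
    """
    if n_per_class < 2 or n_groups < 2:
        raise ValueError("need n_per_class >= 2 and n_groups >= 2")
    out_dir = os.path.abspath(os.fspath(out_dir))
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    rng = np.random.default_rng(seed)

    # per-group appearance parameters, groups alternate classes
    groups = []
    for g in range(n_groups):
        groups.append({
            "id": f"g{g:03d}",
            "label": g % 2,
            "angle": rng.uniform(0.0, np.pi),
            "freq": rng.uniform(2.5, 5.5),
            "n_blobs": int(rng.integers(3, 8)),
            "width": rng.uniform(0.12, 0.30),
            "gain": rng.uniform(0.85, 1.15),
        })
    per_class_groups = [[g for g in groups if g["label"] == c] for c in (0, 1)]
    if not per_class_groups[0] or not per_class_groups[1]:
        raise ValueError("n_groups must give both classes at least one group")

    records = []
    counter = 0
    for label in (0, 1):
        pool = per_class_groups[label]
        for _ in range(n_per_class):
            grp = pool[int(rng.integers(len(pool)))]
            if label == 0:
                img = _stripes_image(image_size,
                                     grp["angle"] + rng.normal(0.0, 0.08),
                                     grp["freq"], rng.uniform(0, 2 * np.pi),
                                     rng)
            else:
                img = _blobs_image(image_size, grp["n_blobs"], grp["width"],
                                   rng)
            img = np.clip(img * grp["gain"], 0.0, 1.0)
            image_id = f"img_{counter:05d}"
            counter += 1
            fname = os.path.join("images", f"{image_id}.png")
            _save(img, os.path.join(out_dir, fname))
            records.append(ImageRecord(
                image_id=image_id,
                filepath=os.path.join(out_dir, fname),
                observed_label=label,
                group_id=grp["id"],
                true_label=label,
                noise_tag="clean",
            ))
    return DatasetManifest(records, CLASS_NAMES)


def inject_intra_class_noise(manifest: DatasetManifest, n_per_class: int,
                             seed: int) -> DatasetManifest:
    """Flip the observed label of exactly ``n_per_class`` clean records per
    class (tagging them ``intra_label``); the image files and true labels
    are untouched and the record count is unchanged."""
    if n_per_class < 0:
        raise ValueError("n_per_class must be non-negative")
    if n_per_class == 0:
        return DatasetManifest(list(manifest.records), manifest.class_names)
    rng = np.random.default_rng(seed)
    chosen: set[str] = set()
    for label in (0, 1):
        pool = [r.image_id for r in manifest
                if r.observed_label == label and r.noise_tag == "clean"]
        if len(pool) < n_per_class:
            raise ValueError(
                f"class {label} has only {len(pool)} clean records, "
                f"cannot flip {n_per_class}")
        chosen.update(rng.choice(pool, size=n_per_class, replace=False))
    records = []
    for r in manifest:
        if r.image_id in chosen:
            records.append(r.replace(observed_label=1 - r.observed_label,
                                     noise_tag="intra_label"))
        else:
            records.append(r)
    return DatasetManifest(records, manifest.class_names)


def inject_extra_class_noise(manifest: DatasetManifest, n_per_class: int,
                             seed: int,
                             out_dir: str | os.PathLike | None = None
                             ) -> DatasetManifest:
    """Append ``n_per_class`` out-of-class distractor images per class
    (a third parametric family), labeled as that class and tagged
    ``extra_label`` with no true label.  Grows the manifest by
    ``2 * n_per_class`` records."""
    if n_per_class < 0:
        raise ValueError("n_per_class must be non-negative")
    if n_per_class == 0:
        return DatasetManifest(list(manifest.records), manifest.class_names)
    if out_dir is None:
        if not manifest.records:
            raise ValueError("cannot infer out_dir from an empty manifest")
        out_dir = os.path.dirname(os.path.dirname(
            os.path.abspath(manifest.records[0].filepath)))
    out_dir = os.path.abspath(os.fspath(out_dir))
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    # infer image size from an existing record if possible
    size = 32
    for r in manifest:
        try:
            with Image.open(r.filepath) as im:
                size = im.size[0]
            break
        except OSError:
            continue
    records = list(manifest.records)
    counter = 0
    for label in (0, 1):
        for _ in range(n_per_class):
            image_id = f"xtra_{counter:05d}"
            counter += 1
            img = _checker_image(size, int(rng.integers(4, 9)), rng)
            fname = os.path.join("images", f"{image_id}.png")
            path = os.path.join(os.fspath(out_dir), fname)
            _save(img, path)
            records.append(ImageRecord(
                image_id=image_id,
                filepath=path,
                observed_label=label,
                group_id=f"xgrp_{counter % 7:02d}",
                true_label=None,
                noise_tag="extra_label",
            ))
    return DatasetManifest(records, manifest.class_names)


def _degrade(img: np.ndarray, mode: int, rng: np.random.Generator
             ) -> np.ndarray:
    """Apply one background degradation: 0 heavy blur, 1 occluding
    rectangles, 2 target shrunk to <= 10% of the frame."""
    size = img.shape[0]
    if mode == 0:
        return gaussian_filter(img, sigma=(size / 10.0, size / 10.0, 0.0))
    if mode == 1:
        out = img.copy()
        for _ in range(3):
            h = int(rng.integers(size // 4, size // 2))
            w = int(rng.integers(size // 4, size // 2))
            y0 = int(rng.integers(0, size - h))
            x0 = int(rng.integers(0, size - w))
            out[y0:y0 + h, x0:x0 + w] = rng.uniform(0.0, 0.15)
        return out
    # shrink: paste a <=10%-area thumbnail of the target on a noisy backdrop
    small = max(2, int(size * 0.30))  # 0.30^2 = 9% of the frame
    thumb = np.asarray(Image.fromarray(
        (img * 255).astype(np.uint8)).resize((small, small), Image.BILINEAR),
        dtype=np.float64) / 255.0
    out = rng.normal(0.45, 0.05, img.shape).clip(0.0, 1.0)
    y0 = int(rng.integers(0, size - small))
    x0 = int(rng.integers(0, size - small))
    out[y0:y0 + small, x0:x0 + small] = thumb
    return out


def degrade_background(manifest: DatasetManifest, fraction: float,
                       seed: int) -> DatasetManifest:
    """Rewrite a random ``fraction`` of the images with one of three
    degradations (blur / occlusion / shrunken target) and tag them
    ``background``.  Labels are untouched — these are low-quality images,
    not mislabeled ones."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n = int(round(fraction * len(manifest)))
    if n == 0:
        return DatasetManifest(list(manifest.records), manifest.class_names)
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(manifest.ids(), size=n, replace=False))
    records = []
    for r in manifest:
        if r.image_id in chosen:
            with Image.open(r.filepath) as im:
                img = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
            mode = int(rng.integers(0, 3))
            _save(np.clip(_degrade(img, mode, rng), 0.0, 1.0), r.filepath)
            records.append(r.replace(noise_tag="background"))
        else:
            records.append(r)
    return DatasetManifest(records, manifest.class_names)


def split_by_group(manifest: DatasetManifest,
                   fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                   seed: int = 0
                   ) -> tuple[DatasetManifest, DatasetManifest, DatasetManifest]:
    """Group-disjoint train/validation/test split.

    Whole groups are assigned greedily (largest group first, to the split
    with the largest remaining image deficit), so every group's images land
    in exactly one split and split sizes approach the target fractions.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    group_ids = sorted({r.group_id for r in manifest.records})
    if len(group_ids) < 3:
        raise ValueError("need at least 3 groups for a 3-way split")
    sizes = {g: 0 for g in group_ids}
    for r in manifest:
        sizes[r.group_id] += 1
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(group_ids))
    order.sort(key=lambda g: -sizes[g])  # stable: big groups first, ties random
    total = len(manifest)
    deficit = [f * total for f in fractions]
    assign: dict[str, int] = {}
    for g in order:
        k = int(np.argmax(deficit))
        assign[g] = k
        deficit[k] -= sizes[g]
    outs = []
    for k in range(3):
        recs = [r for r in manifest if assign[r.group_id] == k]
        outs.append(DatasetManifest(recs, manifest.class_names))
    return tuple(outs)  # type: ignore[return-value]
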