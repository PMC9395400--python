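"""Iterative train-flag-delete screening of a noisy two-class dataset.

The method rests on a low-density-boundary argument: a classifier trained
briefly on the full noisy set learns each class's common features from the
high-density regions first, so after a short training run the images it
still misclassifies are disproportionately the mislabeled and degraded ones.
One screening round therefore (1) trains a fresh network on everything,
(2) reclassifies the training set, and (3) deletes the misclassified images.
Rounds repeat until the flagged proportion falls below a threshold, a round
cap is hit, or a class would be exhausted.

Training details: cross-entropy loss, AdamW optimiser, batches of 32,
no augmentation, and a plateau rule — whenever the mean loss over the most
recent ``plateau_window`` batches fails to drop below the mean over the
preceding window, the learning rate is halved.  The model is re-initialised
from scratch each round (seed = ``base_seed + round_index``) so residual
noise memorised in one round cannot carry into the next; fixed seeds make
whole runs bit-reproducible.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Protocol, Sequence

import numpy as np

from . import data, nn
from .manifest import DatasetManifest, write_manifest
from .model_zoo import ArchitectureSpec, build_model

log = logging.getLogger(__name__)


class Classifier(Protocol):
    """Anything that maps an image batch (N,3,H,W) to class indices (N,)."""

    def predict(self, x: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class CleanerConfig:
    """Knobs of the screening loop.  Defaults follow the method's training
    protocol (batch 32, 224x224 input, AdamW, halve-on-plateau over 200-batch
    windows); rounds and stopping are set for a ~3% noise regime."""

    max_rounds: int = 10
    stop_threshold: float = 0.005
    epochs_per_round: int = 5
    batch_size: int = 32
    image_size: int = 224
    initial_learning_rate: float = 1e-3
    plateau_window: int = 200
    lr_halving_factor: float = 0.5
    min_learning_rate: float = 1e-6
    base_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.stop_threshold < 1.0:
            raise ValueError("stop_threshold must be in (0, 1)")
        if self.batch_size < 1 or self.max_rounds < 1:
            raise ValueError("batch_size and max_rounds must be >= 1")


@dataclass(frozen=True)
class RoundResult:
    round_index: int
    flagged_ids: frozenset[str]
    dataset_size_before: int
    flagged_fraction: float
    final_learning_rate: float


@dataclass
class CleaningReport:
    """Outcome of a full screening run."""

    rounds: list[RoundResult] = field(default_factory=list)
    deleted_ids: set[str] = field(default_factory=set)
    stop_reason: str = "max_rounds"
    surviving_manifest: DatasetManifest | None = None
    read_errors: dict[str, str] = field(default_factory=dict)
    config: CleanerConfig | None = None

    def to_dict(self) -> dict:
        return {
            "stop_reason": self.stop_reason,
            "deleted_ids": sorted(self.deleted_ids),
            "read_errors": dict(sorted(self.read_errors.items())),
            "config": asdict(self.config) if self.config else None,
            "rounds": [{
                "round_index": r.round_index,
                "dataset_size_before": r.dataset_size_before,
                "flagged_count": len(r.flagged_ids),
                "flagged_fraction": r.flagged_fraction,
                "final_learning_rate": r.final_learning_rate,
                "flagged_ids": sorted(r.flagged_ids),
            } for r in self.rounds],
        }

    def save(self, out_dir: str | os.PathLike) -> None:
        """Write report JSON plus surviving/deleted manifests as CSV."""
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
        if self.surviving_manifest is not None:
            write_manifest(self.surviving_manifest,
                           os.path.join(out_dir, "surviving.csv"))


def update_learning_rate(loss_history: Sequence[float], current_lr: float,
                         config: CleanerConfig) -> float:
    """Halve-on-plateau rule over non-overlapping loss windows.

    Evaluated only when ``len(loss_history)`` is a multiple of
    ``plateau_window`` and at least two windows exist; the rate is halved
    when the latest window's mean loss is not lower than the preceding
    window's, and never drops below ``min_learning_rate``.
    """
    w = config.plateau_window
    n = len(loss_history)
    if n < 2 * w or n % w:
        return current_lr
    recent = float(np.mean(loss_history[n - w:]))
    previous = float(np.mean(loss_history[n - 2 * w:n - w]))
    if recent >= previous:
        return max(current_lr * config.lr_halving_factor,
                   config.min_learning_rate)
    return current_lr


class _TrainedModel:
    """A trained network plus its inference-mode ``predict``."""

    def __init__(self, model: nn.Sequential, final_learning_rate: float,
                 loss_history: list[float]):
        self.model = model
        self.final_learning_rate = final_learning_rate
        self.loss_history = loss_history

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        # argmax breaks exact logit ties toward class 0 (first index)
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.model.forward(x[i:i + batch_size], train=False)
            out.append(np.argmax(logits, axis=1))
        return np.concatenate(out) if out else np.zeros(0, dtype=np.int64)


def train_one_round(manifest: DatasetManifest, spec: ArchitectureSpec,
                    config: CleanerConfig, round_index: int,
                    images: dict[str, np.ndarray] | None = None
                    ) -> _TrainedModel:
    """Train a freshly initialised network on the full manifest.

    ``images`` may carry pre-decoded arrays (id -> (3,H,W)); otherwise files
    are read from disk.  Raises ``ValueError`` when a class is absent.
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    n0, n1 = manifest.class_counts()
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present for training")
    if images is None:
        images, _errors = data.load_images(manifest, config.image_size)
    x, y, _ids = data.stack(manifest, images)

    seed = config.base_seed + round_index
    model = build_model(spec, seed=seed)
    rng = np.random.default_rng(seed)
    opt = nn.AdamW(model, lr=config.initial_learning_rate)
    losses: list[float] = []
    for _epoch in range(config.epochs_per_round):
        order = rng.permutation(len(x))
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = model.forward(x[idx], train=True)
            loss, glogits = nn.softmax_cross_entropy(logits, y[idx])
            model.backward(glogits)
            opt.step()
            losses.append(loss)
            opt.lr = update_learning_rate(losses, opt.lr, config)
    return _TrainedModel(model, opt.lr, losses)


def flag_misclassified(classifier: Classifier, manifest: DatasetManifest,
                       image_size: int = 224,
                       images: dict[str, np.ndarray] | None = None,
                       ) -> tuple[set[str], dict[str, str]]:
    """Ids whose predicted class differs from the observed label.

    Unreadable images are treated as flagged (they are background-noise
    candidates by definition) and reported in the second return value.
    Deterministic: inference mode, no augmentation, ties go to class 0.
    """
    errors: dict[str, str] = {}
    if images is None:
        images, errors = data.load_images(manifest, image_size)
    else:
        errors = {r.image_id: "image not provided" for r in manifest
                  if r.image_id not in images}
    x, y, ids = data.stack(manifest, images)
    flagged = set(errors)
    if len(ids):
        pred = classifier.predict(x)
        flagged.update(i for i, p, t in zip(ids, pred, y) if p != t)
    return flagged, errors


def clean(manifest: DatasetManifest, spec: ArchitectureSpec,
          config: CleanerConfig) -> CleaningReport:
    """Run the full iterative screening loop and return its report.

    Deletion is permanent within a run; per-round flagged sets are disjoint
    and their union is ``deleted_ids``, so ``|surviving| + |deleted|``
    always equals the input size.
    """
    n0, n1 = manifest.class_counts()
    if n0 < 2 or n1 < 2:
        raise ValueError("need at least 2 images per class")

    report = CleaningReport(config=config)
    images, read_errors = data.load_images(manifest, config.image_size)
    report.read_errors = read_errors
    current = manifest
    stop_reason = "max_rounds"
    for round_index in range(1, config.max_rounds + 1):
        n0, n1 = current.class_counts()
        if n0 == 0 or n1 == 0:
            stop_reason = "class_exhausted"
            break
        trainable = current.drop(read_errors)
        n0, n1 = trainable.class_counts()
        if n0 == 0 or n1 == 0:  # all readable images of one class are gone
            stop_reason = "class_exhausted"
            break
        trained = train_one_round(trainable, spec, config, round_index,
                                  images=images)
        flagged, _ = flag_misclassified(trained, current, config.image_size,
                                        images=images)
        size_before = len(current)
        fraction = len(flagged) / size_before
        report.rounds.append(RoundResult(
            round_index=round_index,
            flagged_ids=frozenset(flagged),
            dataset_size_before=size_before,
            flagged_fraction=fraction,
            final_learning_rate=trained.final_learning_rate,
        ))
        report.deleted_ids.update(flagged)
        current = current.drop(flagged)
        log.info("round %d: size %d, flagged %d (%.3f%%), lr %.2e",
                 round_index, size_before, len(flagged), 100 * fraction,
                 trained.final_learning_rate)
        if fraction < config.stop_threshold:
            stop_reason = "threshold_reached"
            break
        n0, n1 = current.class_counts()
        if n0 == 0 or n1 == 0:
            stop_reason = "class_exhausted"
            break
    report.stop_reason = stop_reason
    report.surviving_manifest = current
    return report
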