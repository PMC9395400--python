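"""Screening evaluation indicators.

Three percentages summarise how well a cleaning run screened a dataset whose
true errors are known:

* error rate ``E_rate = 100 * ATW / ALL`` — the fraction of the dataset that
  is truly erroneous (ATW = actual true wrong, ALL = dataset size);
* filtering accuracy ``F_acc = 100 * TW / MW`` — the precision of the flagged
  set (MW = flagged "maybe wrong", TW = flagged images that are true errors);
* filtering recall ``F_rec = 100 * TW / ATW`` — the fraction of true errors
  the screen recovered.

Percentages are carried on the 0–100 scale as exact floats; rounding happens
only at display time (:func:`format_percent`).  This preserves the identity
``F_acc * MW == F_rec * ATW == 100 * TW`` for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

from .manifest import DatasetManifest, ERROR_TAGS


def _check_counts(**counts: int) -> None:
    for name, value in counts.items():
        if value != int(value) or value < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {value}")


def error_rate(atw: int, all_count: int) -> float:
    """Percentage of truly erroneous images in the dataset: 100 * ATW / ALL."""
    _check_counts(atw=atw, all_count=all_count)
    if all_count == 0:
        raise ValueError("all_count must be positive")
    if atw > all_count:
        raise ValueError(f"atw ({atw}) exceeds all_count ({all_count})")
    return 100.0 * atw / all_count


def filtering_accuracy(tw: int, mw: int) -> float:
    """Precision of the flagged set: 100 * TW / MW.

    Undefined (raises) when nothing was flagged.
    """
    _check_counts(tw=tw, mw=mw)
    if mw == 0:
        raise ValueError("mw must be positive: no flagged images, accuracy undefined")
    if tw > mw:
        raise ValueError(f"tw ({tw}) exceeds mw ({mw})")
    return 100.0 * tw / mw


def filtering_recall(tw: int, atw: int) -> float:
    """Fraction of true errors recovered by the screen: 100 * TW / ATW.

    Undefined (raises) when the dataset contains no true errors.
    """
    _check_counts(tw=tw, atw=atw)
    if atw == 0:
        raise ValueError("atw must be positive: no true errors, recall undefined")
    if tw > atw:
        raise ValueError(f"tw ({tw}) exceeds atw ({atw})")
    return 100.0 * tw / atw


def format_percent(value: float, decimals: int = 1) -> str:
    """Round half-away-from-zero to ``decimals`` places, e.g. 48.4375 -> '48.4'.

    ``decimals=0`` gives integer display ('18')."""
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP)
    return str(d)


@dataclass(frozen=True)
class CleaningEvaluation:
    """Counts and derived percentages for one evaluated cleaning run."""

    all_count: int
    atw: int
    mw: int
    tw: int
    e_rate: float
    f_acc: float
    f_rec: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["all"] = d.pop("all_count")
        return d


def evaluate_cleaning(flagged_ids: Iterable[str],
                      manifest: DatasetManifest,
                      error_tags: Sequence[str] = ERROR_TAGS,
                      ) -> CleaningEvaluation:
    """Score a flagged id set against a ground-truth manifest.

    A record is a true error when its noise tag is one of ``error_tags``
    (by default: intra-class flips, out-of-class distractors, and degraded
    backgrounds).  Restrict ``error_tags`` to report per-noise-type results.

    Degenerate denominators (empty flagged set, or no true errors present)
    yield 0.0 for the corresponding percentage in the report; the bare
    :func:`filtering_accuracy` / :func:`filtering_recall` functions raise
    instead.
    """
    flagged = set(flagged_ids)
    by_id = manifest.by_id()
    missing = flagged - by_id.keys()
    if missing:
        raise KeyError(f"flagged ids not in manifest: {sorted(missing)[:5]}")
    bad = set(error_tags) - set(ERROR_TAGS)
    if bad:
        raise ValueError(f"unknown error tags: {sorted(bad)}")
    if len(manifest) == 0:
        raise ValueError("manifest is empty")

    tags = set(error_tags)
    true_errors = {r.image_id for r in manifest if r.noise_tag in tags}
    all_count = len(manifest)
    atw = len(true_errors)
    mw = len(flagged)
    tw = len(flagged & true_errors)
    return CleaningEvaluation(
        all_count=all_count, atw=atw, mw=mw, tw=tw,
        e_rate=error_rate(atw, all_count),
        f_acc=filtering_accuracy(tw, mw) if mw else 0.0,
        f_rec=filtering_recall(tw, atw) if atw else 0.0,
    )
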