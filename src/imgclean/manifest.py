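"""Dataset manifests: one row per image, with observed label, patient-like
group id, and (for benchmark data) the ground-truth label and noise tag.

The manifest CSV is the single interchange format of the package.  Layout::

    # classes: <class0>,<class1>
    image_id,filepath,observed_label,group_id,true_label,noise_tag
    img_00000,images/img_00000.png,stripes,g03,stripes,clean
    ...

Labels are stored by class *name*; the class listed first on the
``# classes:`` line is index 0.  ``true_label`` is empty for records whose
true class is outside the two dataset classes (out-of-class distractors) or
unknown (real data).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd

#: Recognised noise tags. ``clean`` means the observed label is trusted.
NOISE_TAGS = ("clean", "intra_label", "extra_label", "background")

#: Tags counted as "true error" images when evaluating a cleaning run.
ERROR_TAGS = ("intra_label", "extra_label", "background")

_COLUMNS = ["image_id", "filepath", "observed_label", "group_id",
            "true_label", "noise_tag"]


@dataclass(frozen=True)
class ImageRecord:
    """A single image's identity and annotations.

    ``observed_label`` / ``true_label`` are class indices (0 or 1);
    ``true_label`` is ``None`` when the true class is unknown or lies
    outside the two dataset classes.
    """

    image_id: str
    filepath: str
    observed_label: int
    group_id: str
    true_label: int | None = None
    noise_tag: str = "clean"

    def __post_init__(self) -> None:
        if self.noise_tag not in NOISE_TAGS:
            raise ValueError(f"unknown noise_tag {self.noise_tag!r}")
        if self.noise_tag == "clean" and self.true_label is not None \
                and self.true_label != self.observed_label:
            raise ValueError(
                f"{self.image_id}: clean record with observed_label != true_label")
        if self.noise_tag == "intra_label" and self.true_label is not None \
                and self.true_label == self.observed_label:
            raise ValueError(
                f"{self.image_id}: intra_label record whose labels agree")

    def replace(self, **kw) -> "ImageRecord":
        return dataclasses.replace(self, **kw)


@dataclass
class DatasetManifest:
    """Ordered collection of :class:`ImageRecord` plus the two class names."""

    records: list[ImageRecord] = field(default_factory=list)
    class_names: tuple[str, str] = ("class0", "class1")

    def __post_init__(self) -> None:
        if len(self.class_names) != 2:
            raise ValueError("exactly two class names are required")
        seen: set[str] = set()
        for r in self.records:
            if r.image_id in seen:
                raise ValueError(f"duplicate image_id {r.image_id!r}")
            seen.add(r.image_id)
            if r.observed_label not in (0, 1):
                raise ValueError(
                    f"{r.image_id}: observed_label must be 0 or 1")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ImageRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.image_id for r in self.records]

    def by_id(self) -> dict[str, ImageRecord]:
        return {r.image_id: r for r in self.records}

    def class_counts(self) -> tuple[int, int]:
        n0 = sum(1 for r in self.records if r.observed_label == 0)
        return n0, len(self.records) - n0

    def subset(self, ids: Iterable[str]) -> "DatasetManifest":
        """Records whose id is in ``ids``, preserving manifest order."""
        keep = set(ids)
        return DatasetManifest(
            [r for r in self.records if r.image_id in keep], self.class_names)

    def drop(self, ids: Iterable[str]) -> "DatasetManifest":
        omit = set(ids)
        return DatasetManifest(
            [r for r in self.records if r.image_id not in omit],
            self.class_names)

    def has_ground_truth(self) -> bool:
        """True when every record carries a noise tag usable as ground truth
        (any manifest does syntactically; real-data manifests that were not
        produced by the noise lab are all-'clean' and carry no information —
        callers decide whether that is meaningful)."""
        return all(r.noise_tag in NOISE_TAGS for r in self.records)


def write_manifest(manifest: DatasetManifest, path: str | os.PathLike) -> None:
    """Write the manifest CSV (class names on a leading ``# classes:`` line)."""
    rows = []
    for r in manifest.records:
        rows.append({
            "image_id": r.image_id,
            "filepath": r.filepath,
            "observed_label": manifest.class_names[r.observed_label],
            "group_id": r.group_id,
            "true_label": "" if r.true_label is None
                          else manifest.class_names[r.true_label],
            "noise_tag": r.noise_tag,
        })
    df = pd.DataFrame(rows, columns=_COLUMNS)
    with open(path, "w", newline="") as fh:
        fh.write(f"# classes: {manifest.class_names[0]},{manifest.class_names[1]}\n")
        df.to_csv(fh, index=False)


def read_manifest(path: str | os.PathLike) -> DatasetManifest:
    """Read a manifest CSV written by :func:`write_manifest`.

    Relative image paths are resolved against the CSV's directory.
    """
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# classes:"):
            raise ValueError(
                f"{path}: missing '# classes:' header line")
        names = tuple(s.strip() for s in first.split(":", 1)[1].split(","))
        if len(names) != 2:
            raise ValueError(f"{path}: expected exactly two class names")
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    if list(df.columns) != _COLUMNS:
        raise ValueError(f"{path}: unexpected columns {list(df.columns)}")
    index = {name: i for i, name in enumerate(names)}
    root = os.path.dirname(os.path.abspath(path))
    records = []
    for row in df.itertuples(index=False):
        fp = row.filepath
        if fp and not os.path.isabs(fp):
            fp = os.path.join(root, fp)
        records.append(ImageRecord(
            image_id=row.image_id,
            filepath=fp,
            observed_label=index[row.observed_label],
            group_id=row.group_id,
            true_label=None if row.true_label == "" else index[row.true_label],
            noise_tag=row.noise_tag,
        ))
    return DatasetManifest(records, names)  # type: ignore[arg-type]


def strip_ground_truth(manifest: DatasetManifest) -> DatasetManifest:
    """Blank true labels and noise tags — the 'observed only' view a cleaning
    run would see on real data."""
    recs = [r.replace(true_label=None, noise_tag="clean")
            for r in manifest.records]
    return DatasetManifest(recs, manifest.class_names)


def manifest_from_folders(root: str | os.PathLike,
                          class_names: Sequence[str] | None = None,
                          group_depth: int = 1) -> DatasetManifest:
    """Build a manifest from a ``root/<class>/[group/]image.png`` folder tree.

    Subfolder names under ``root`` are the class names (sorted, or in the
    order given by ``class_names``).  With ``group_depth=1`` each immediate
    subfolder of a class folder is a group; images sitting directly in the
    class folder each form their own group.
    """
    root = os.fspath(root)
    found = sorted(d for d in os.listdir(root)
                   if os.path.isdir(os.path.join(root, d)))
    if class_names is None:
        class_names = found
    if len(class_names) != 2:
        raise ValueError(f"expected exactly 2 class folders, found {found}")
    exts = {".png", ".jpg", ".jpeg", ".bmp"}
    records = []
    for label, cname in enumerate(class_names):
        cdir = os.path.join(root, cname)
        for dirpath, _dirnames, filenames in sorted(os.walk(cdir)):
            for fname in sorted(filenames):
                if os.path.splitext(fname)[1].lower() not in exts:
                    continue
                rel = os.path.relpath(dirpath, cdir)
                if group_depth >= 1 and rel != ".":
                    group = f"{cname}/{rel.split(os.sep)[0]}"
                else:
                    group = f"{cname}/{os.path.splitext(fname)[0]}"
                stem = os.path.splitext(fname)[0]
                prefix = "" if rel == "." else rel.replace(os.sep, "_") + "_"
                records.append(ImageRecord(
                    image_id=f"{cname}_{prefix}{stem}",
                    filepath=os.path.join(dirpath, fname),
                    observed_label=label,
                    group_id=group,
                ))
    return DatasetManifest(records, tuple(class_names))  # type: ignore[arg-type]
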