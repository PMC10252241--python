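"""Dataset ingestion, augmentation, class balancing, splitting, regrouping.

A :class:`GradedImageSet` is a flat list of records (image array, integer
grade, origin flag, split assignment).  Augmentation is only ever applied to
training records, so augmented samples can never leak into validation/test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "ImageRecord",
    "GradedImageSet",
    "AugmentPolicy",
    "augment_image",
    "balance_classes",
    "split_dataset",
    "regroup_labels",
    "load_image_tree",
    "load_manifest",
    "save_dataset",
]

TASKS = ("five", "three", "two")

# grade -> task label; {0,1} are "healthy" (grade 1 is "doubtful/healthy")
_THREE_CLASS = {0: 0, 1: 0, 2: 1, 3: 1, 4: 2}  # healthy / moderate / severe
_TWO_CLASS = {0: 0, 1: 0, 2: 1, 3: 1, 4: 1}  # healthy / unhealthy


@dataclass
class ImageRecord:
    image: np.ndarray  # HxW uint8 or float
    grade: int
    origin: str = "original"  # original | augmented
    split: str = "unassigned"  # train | val | test | unassigned
    path: str = ""


@dataclass
class GradedImageSet:
    records: list[ImageRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> "GradedImageSet":
        return GradedImageSet([r for r in self.records if r.split == split])

    def class_counts(self, split: str | None = None) -> dict[int, int]:
        counts: dict[int, int] = {}
        for r in self.records:
            if split is None or r.split == split:
                counts[r.grade] = counts.get(r.grade, 0) + 1
        return dict(sorted(counts.items()))

    def grades(self) -> list[int]:
        return [r.grade for r in self.records]

    def arrays(self, task: str = "five") -> tuple[np.ndarray, np.ndarray]:
        """Stacked float32 images in [0,1] and task-regrouped labels."""
        imgs = np.stack([np.asarray(r.image, dtype=np.float32) for r in self.records])
        if imgs.max() > 1.5:
            imgs /= 255.0
        labels = np.asarray(regroup_labels(self.grades(), task), dtype=np.int64)
        return imgs, labels


@dataclass(frozen=True)
class AugmentPolicy:
    """Random-transform ranges; defaults follow the tuned augmentation table."""

    horizontal_flip: bool = True
    rotation_range: float = 25.0  # degrees, drawn uniform in [-r, r]
    width_shift_range: float = 0.22  # fraction of width
    height_shift_range: float = 0.23  # fraction of height
    zoom_range: float = 0.25  # zoom factor drawn in [1-z, 1+z]

    def is_identity(self) -> bool:
        return not self.horizontal_flip and not any(
            (self.rotation_range, self.width_shift_range,
             self.height_shift_range, self.zoom_range)
        )


def augment_image(image: np.ndarray, policy: AugmentPolicy, seed: int) -> np.ndarray:
    """One random flip/rotate/shift/zoom draw; shape-preserving, seeded.

    Geometry is applied as a single inverse affine map (bilinear
    interpolation, nearest-edge fill) so repeated resampling artifacts are
    avoided.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot augment an empty image")
    if image.ndim != 2:
        raise ValueError("expected a single-channel HxW image")
    if policy.is_identity():
        return image.copy()

    rng = np.random.default_rng(seed)
    flip = policy.horizontal_flip and rng.random() < 0.5
    theta = math.radians(rng.uniform(-policy.rotation_range, policy.rotation_range))
    tx = rng.uniform(-policy.width_shift_range, policy.width_shift_range) * image.shape[1]
    ty = rng.uniform(-policy.height_shift_range, policy.height_shift_range) * image.shape[0]
    zoom = rng.uniform(1.0 - policy.zoom_range, 1.0 + policy.zoom_range)

    src = image[:, ::-1] if flip else image
    # output (row, col) -> input coords: undo zoom+rotation about the center,
    # then undo the translation
    cos, sin = math.cos(theta), math.sin(theta)
    inv = np.array([[cos, -sin], [sin, cos]]) / zoom
    center = (np.array(src.shape) - 1) / 2.0
    offset = center - inv @ (center + np.array([ty, tx]))
    out = ndimage.affine_transform(
        src.astype(np.float64), inv, offset=offset, order=1, mode="nearest"
    )
    if np.issubdtype(image.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255)
    return out.astype(image.dtype)


def regroup_labels(grades, task: str):
    """Map 0-4 grades onto the active task's label set.

    ``five`` is the identity; ``three`` folds {0,1}/{2,3}/{4} into
    healthy/moderate/severe; ``two`` folds {0,1}/{2,3,4} into
    healthy/unhealthy.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}, got {task!r}")
    out = []
    for g in grades:
        g = int(g)
        if not 0 <= g <= 4:
            raise ValueError(f"grade {g} outside 0..4")
        if task == "five":
            out.append(g)
        elif task == "three":
            out.append(_THREE_CLASS[g])
        else:
            out.append(_TWO_CLASS[g])
    return out


def num_classes_for(task: str) -> int:
    return {"five": 5, "three": 3, "two": 2}[task]


def balance_classes(
    dataset: GradedImageSet,
    target: int,
    policy: AugmentPolicy | None = None,
    seed: int = 0,
) -> GradedImageSet:
    """Equalize the training split at exactly ``target`` records per class.

    Classes below target are topped up with augmented copies of randomly
    chosen same-class originals; classes above target are randomly
    subsampled without replacement.  Operates on ``split == "train"``
    records (or on every record if nothing is assigned yet, in which case
    the result is marked train).  Non-train records pass through untouched.
    """
    policy = policy or AugmentPolicy()
    rng = np.random.default_rng(seed)
    has_train = any(r.split == "train" for r in dataset.records)
    train = [r for r in dataset.records if r.split == "train"] if has_train else [
        replace(r, image=r.image, split="train") for r in dataset.records
    ]
    rest = [r for r in dataset.records if r.split != "train"] if has_train else []

    if not train:
        raise ValueError("no training records to balance")
    by_class: dict[int, list[ImageRecord]] = {}
    for r in train:
        by_class.setdefault(r.grade, []).append(r)

    out: list[ImageRecord] = []
    for grade in sorted(by_class):
        originals = by_class[grade]
        if not originals:
            raise ValueError(f"class {grade} has no original training records")
        n = len(originals)
        if n >= target:
            keep_idx = rng.choice(n, size=target, replace=False)
            out.extend(originals[i] for i in sorted(keep_idx))
        else:
            out.extend(originals)
            src_idx = rng.integers(0, n, size=target - n)
            for i in src_idx:
                src = originals[int(i)]
                aug_seed = int(rng.integers(0, 2**32))
                out.append(
                    ImageRecord(
                        image=augment_image(np.asarray(src.image), policy, aug_seed),
                        grade=grade,
                        origin="augmented",
                        split="train",
                    )
                )
    return GradedImageSet(out + rest)


def split_dataset(
    dataset: GradedImageSet,
    fractions: tuple[float, float, float],
    seed: int = 0,
) -> GradedImageSet:
    """Stratified random train/val/test assignment.

    Per-class counts follow the requested fractions by the largest-remainder
    rule; every class is represented in every subset (classes need at least
    3 members).  Returns a new set; every input record is assigned exactly
    once.
    """
    if len(fractions) != 3:
        raise ValueError("fractions must be (train, val, test)")
    if any(f <= 0 for f in fractions):
        raise ValueError("all three split fractions must be > 0")
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")

    rng = np.random.default_rng(seed)
    by_class: dict[int, list[int]] = {}
    for idx, r in enumerate(dataset.records):
        by_class.setdefault(r.grade, []).append(idx)

    names = ("train", "val", "test")
    assignment: dict[int, str] = {}
    for grade in sorted(by_class):
        idxs = np.array(by_class[grade])
        rng.shuffle(idxs)
        n = len(idxs)
        raw = [f * n for f in fractions]
        counts = [int(math.floor(x)) for x in raw]
        remainders = sorted(
            range(3), key=lambda i: (raw[i] - counts[i], fractions[i]), reverse=True
        )
        for i in remainders[: n - sum(counts)]:
            counts[i] += 1
        # guarantee representation: steal from the largest allocation
        for i in range(3):
            while counts[i] == 0:
                j = int(np.argmax(counts))
                if counts[j] <= 1:
                    raise ValueError(
                        f"class {grade} too small ({n}) to appear in all subsets"
                    )
                counts[j] -= 1
                counts[i] += 1
        start = 0
        for name, cnt in zip(names, counts):
            for idx in idxs[start : start + cnt]:
                assignment[int(idx)] = name
            start += cnt

    new_records = [
        replace(r, split=assignment[i]) for i, r in enumerate(dataset.records)
    ]
    return GradedImageSet(new_records)


# ------------------------------------------------------------------------ IO

def load_image_tree(root: str | Path) -> GradedImageSet:
    """Read a directory-per-class tree of PNG/JPEG images (folder name is
    the grade, optionally prefixed, e.g. ``3`` or ``grade_3``)."""
    root = Path(root)
    records = []
    for sub in sorted(root.iterdir()):
        if not sub.is_dir():
            continue
        grade = int(sub.name.split("_")[-1])
        for img_path in sorted(sub.glob("*")):
            if img_path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            img = np.asarray(Image.open(img_path).convert("L"))
            records.append(ImageRecord(img, grade, path=str(img_path)))
    if not records:
        raise ValueError(f"no images found under {root}")
    return GradedImageSet(records)


def load_manifest(csv_path: str | Path) -> GradedImageSet:
    """Read a CSV manifest with columns path,grade[,origin,split]."""
    df = pd.read_csv(csv_path)
    base = Path(csv_path).parent
    records = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        img = np.asarray(Image.open(p).convert("L"))
        records.append(
            ImageRecord(
                img,
                int(row.grade),
                origin=getattr(row, "origin", "original"),
                split=getattr(row, "split", "unassigned"),
                path=str(p),
            )
        )
    return GradedImageSet(records)


def save_dataset(dataset: GradedImageSet, out_dir: str | Path) -> Path:
    """Write PNGs into grade folders plus a manifest CSV; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    counters: dict[int, int] = {}
    for r in dataset.records:
        sub = out_dir / f"grade_{r.grade}"
        sub.mkdir(exist_ok=True)
        i = counters.get(r.grade, 0)
        counters[r.grade] = i + 1
        name = f"{r.origin}_{i:05d}.png"
        img = np.asarray(r.image)
        if img.dtype != np.uint8:
            img = np.clip(img * 255 if img.max() <= 1.5 else img, 0, 255).astype(np.uint8)
        Image.fromarray(img).save(sub / name)
        rel = f"grade_{r.grade}/{name}"
        rows.append({"path": rel, "grade": r.grade, "origin": r.origin, "split": r.split})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
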