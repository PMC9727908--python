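"""Assemble the balanced 17-class training corpus.

Each scored phantom image contributes 16 sub-images.  Reviewer points are
binarized (barely visible counts as visible), a visible sub-image takes
the class of its own position, and every non-visible sub-image falls into
the shared ``nonv`` category.  After a 90:10 image-level train/validation
split, the training pool is balanced by sampling-with-replacement plus
random rotation so that every visible class holds exactly 2N sub-images
and the non-visible class 6N, where N is the number of training images
(38N sub-images in total; with the full 2,640-image corpus this is
2,376 training images and 90,288 sub-images).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augment import rotation_augment
from .classes import CLASS_NAMES, NONV, position_to_class
from .errors import ClassStarvedError, InvalidArgumentError
from .preprocess import SubImage

VISIBLE_CLASS_FACTOR = 2  # visible classes are brought to 2N sub-images
NONV_CLASS_FACTOR = 6  # the non-visible class to 6N
TOTAL_FACTOR = 16 * VISIBLE_CLASS_FACTOR + NONV_CLASS_FACTOR  # 38N


@dataclass
class LabeledSubImage:
    """A sub-image with its 17-way class label and split assignment."""

    sub: SubImage
    label: str
    split: str = "train"

    def __post_init__(self) -> None:
        if self.label not in CLASS_NAMES:
            raise InvalidArgumentError(f"unknown class label {self.label!r}")
        if self.split not in ("train", "val", "test"):
            raise InvalidArgumentError(f"unknown split {self.split!r}")
        if self.label != NONV and position_to_class(self.sub.position) != self.label:
            raise InvalidArgumentError(
                f"label {self.label} does not match position {self.sub.position}")


@dataclass
class DatasetManifest:
    """Bookkeeping for a balanced corpus."""

    counts: dict[str, dict[str, int]]  # split -> class -> count
    n_train_images: int
    visible_target: int
    nonv_target: int
    seed: int

    @property
    def total_train(self) -> int:
        return sum(self.counts.get("train", {}).values())


def binarize_training_score(point: float) -> int:
    """Round a reviewer point to the binary training label.

    Barely-visible (0.5) counts as visible, matching how single-reviewer
    training scores are rounded.
    """
    if point not in (0, 0.5, 1):
        raise InvalidArgumentError(f"point must be 0, 0.5 or 1, got {point}")
    return 0 if point == 0 else 1


def consensus_label(reviewer_points: list[float]) -> int:
    """Median of the reviewers' points, rounded to 0/1 with ties at 0.5 up."""
    if not reviewer_points:
        raise InvalidArgumentError("need at least one reviewer")
    for p in reviewer_points:
        if p not in (0, 0.5, 1):
            raise InvalidArgumentError(f"point must be 0, 0.5 or 1, got {p}")
    med = float(np.median(np.asarray(reviewer_points, dtype=np.float64)))
    return 1 if med >= 0.5 else 0


def assign_class(sub: SubImage, visible: int) -> str:
    """Class of a sub-image: its position's class when visible, else nonv."""
    if visible not in (0, 1):
        raise InvalidArgumentError("visible must be 0 or 1")
    return position_to_class(sub.position) if visible else NONV


def split_images(images: list, ratio: float = 0.9,
                 seed: int | np.random.Generator = 0) -> tuple[list, list]:
    """Random image-level train/validation split; |train| = round(ratio * n)."""
    n = len(images)
    if n < 2:
        raise InvalidArgumentError("need at least two images to split")
    if not 0.0 < ratio < 1.0:
        raise InvalidArgumentError("ratio must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    train_idx = set(order[:n_train].tolist())
    train = [im for i, im in enumerate(images) if i in train_idx]
    val = [im for i, im in enumerate(images) if i not in train_idx]
    return train, val


def balance_and_augment(train_subs: list[LabeledSubImage],
                        seed: int = 0,
                        n_train_images: int | None = None,
                        ) -> tuple[list[LabeledSubImage], DatasetManifest]:
    """Balance the training pool by resampling + random rotation.

    Every drawn member is a rotated (+-3 degrees) copy of an existing
    sub-image of the same class; visible classes are brought to exactly
    2N members and the non-visible class to 6N, N being the number of
    distinct training images (inferred from source ids unless given).
    """
    if not train_subs:
        raise InvalidArgumentError("empty training pool")
    pools: dict[str, list[LabeledSubImage]] = {c: [] for c in CLASS_NAMES}
    for ls in train_subs:
        pools[ls.label].append(ls)
    starved = [c for c, pool in pools.items() if not pool]
    if starved:
        raise ClassStarvedError(f"classes without training examples: {starved}")
    if n_train_images is None:
        sources = {ls.sub.source_id for ls in train_subs}
        n_train_images = len(sources) if sources != {""} else len(train_subs) // 16
    n = int(n_train_images)
    rng = np.random.default_rng(seed)
    out: list[LabeledSubImage] = []
    for cls in CLASS_NAMES:
        target = NONV_CLASS_FACTOR * n if cls == NONV else VISIBLE_CLASS_FACTOR * n
        pool = pools[cls]
        picks = rng.integers(0, len(pool), size=target)
        for i in picks:
            src = pool[int(i)]
            out.append(LabeledSubImage(sub=rotation_augment(src.sub, rng),
                                       label=cls, split="train"))
    counts = {"train": {c: 0 for c in CLASS_NAMES}}
    for ls in out:
        counts["train"][ls.label] += 1
    manifest = DatasetManifest(counts=counts, n_train_images=n,
                               visible_target=VISIBLE_CLASS_FACTOR * n,
                               nonv_target=NONV_CLASS_FACTOR * n, seed=seed)
    return out, manifest


def label_subimages(subs: list[SubImage], points: dict[int, float],
                    split: str = "train") -> list[LabeledSubImage]:
    """Attach binarized visibility labels to one image's 16 sub-images."""
    out = []
    for sub in subs:
        visible = binarize_training_score(points[sub.position])
        out.append(LabeledSubImage(sub=sub, label=assign_class(sub, visible),
                                   split=split))
    return out
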