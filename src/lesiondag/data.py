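"""Dataset preparation: stratified splitting, repeated validation folds,
class-balancing augmentation, and inverse-frequency class weights.

The split convention used throughout: the requested fraction sizes the
*smaller* side per class with round-half-up, so e.g. a 20% test split of class
counts (1113, 6705, 1099) receives (223, 1341, 220) samples.  Class balancing
is planned as the per-class deficit to a target count and executed with label
preserving geometric ops (flips, rotation, width/height shift).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import rotate as _sk_rotate

from .synthetic import LabeledImageSet

__all__ = [
    "SplitPlan",
    "AugmentationPlan",
    "ClassWeights",
    "AUGMENTATION_OPS",
    "stratified_split",
    "make_validation_repeats",
    "plan_augmentation",
    "execute_augmentation",
    "class_weights",
    "prevalence_ratios",
]

#: Augmentation operations available to the balancing planner.
AUGMENTATION_OPS: tuple[str, ...] = ("hflip", "vflip", "rotation", "width_shift", "height_shift")


@dataclass(frozen=True)
class SplitPlan:
    """Held-out fraction, validation fraction, number of repeated validation
    splits, and the seed controlling all of them."""

    test_fraction: float = 0.2
    val_fraction: float = 0.2
    n_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.test_fraction, self.val_fraction):
            if not 0.0 < f < 1.0:
                raise ValueError("fractions must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class AugmentationPlan:
    """Per-class balancing targets, the per-class number of images to
    generate, and a deterministic per-image (op, params) assignment."""

    per_class_targets: dict[int, int]
    per_class_generate: dict[int, int]
    op_pool: tuple[str, ...]
    assignments: dict[int, list[tuple[str, dict]]] = field(default_factory=dict)


@dataclass(frozen=True)
class ClassWeights:
    """Strictly positive per-class loss weights."""

    w: dict[int, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.w.values()):
            raise ValueError("class weights must be strictly positive")

    def as_array(self, K: int | None = None) -> np.ndarray:
        K = K if K is not None else max(self.w) + 1
        return np.array([self.w[c] for c in range(K)])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(
    labels: np.ndarray, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random partition of ``labels``' indices.

    Per class with n_c members, side b receives round-half-up(fraction * n_c)
    members; side a receives the rest.  Both sides are returned sorted, are
    disjoint, and exhaust the indices.  Deterministic for a given seed.
    """
    labels = np.asarray(labels, dtype=int)
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    side_a: list[np.ndarray] = []
    side_b: list[np.ndarray] = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            raise ValueError(f"class {c} has fewer than 2 members")
        n_b = _round_half_up(fraction * len(idx))
        perm = rng.permutation(idx)
        side_b.append(perm[:n_b])
        side_a.append(perm[n_b:])
    return np.sort(np.concatenate(side_a)), np.sort(np.concatenate(side_b))


def make_validation_repeats(
    train_labels: np.ndarray, plan: SplitPlan
) -> list[tuple[np.ndarray, np.ndarray]]:
    """``plan.n_repeats`` independent stratified shuffle splits of the
    training pool at ``plan.val_fraction`` (train side first, then val)."""
    repeats = []
    for r in range(plan.n_repeats):
        sub_seed = int(
            np.random.SeedSequence(entropy=plan.seed, spawn_key=(r,)).generate_state(1)[0]
        )
        repeats.append(stratified_split(train_labels, plan.val_fraction, sub_seed))
    return repeats


def plan_augmentation(
    observed_counts: dict[int, int],
    targets: dict[int, int],
    op_pool: tuple[str, ...] = AUGMENTATION_OPS,
    seed: int = 0,
) -> AugmentationPlan:
    """Plan class balancing: generate max(0, target - observed) images per
    class, each with an op drawn deterministically from ``op_pool``.

    Op parameters (package defaults, configurable at execution): rotation angle
    uniform in +-90 degrees, width/height shift uniform in +-10% with reflect
    padding.
    """
    unknown = set(op_pool) - set(AUGMENTATION_OPS)
    if unknown:
        raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
    if any(t < 0 for t in targets.values()):
        raise ValueError("targets must be >= 0")
    generate = {
        c: max(0, targets[c] - observed_counts.get(c, 0)) for c in sorted(targets)
    }
    rng = np.random.default_rng(seed)
    assignments: dict[int, list[tuple[str, dict]]] = {}
    for c in sorted(generate):
        ops: list[tuple[str, dict]] = []
        for _ in range(generate[c]):
            op = op_pool[rng.integers(len(op_pool))]
            params: dict = {}
            if op == "rotation":
                params["angle"] = float(rng.uniform(-90.0, 90.0))
            elif op in ("width_shift", "height_shift"):
                params["shift"] = float(rng.uniform(-0.1, 0.1))
            ops.append((op, params))
        assignments[c] = ops
    return AugmentationPlan(
        per_class_targets=dict(targets),
        per_class_generate=generate,
        op_pool=tuple(op_pool),
        assignments=assignments,
    )


def apply_augmentation_op(image: np.ndarray, op: str, params: dict) -> np.ndarray:
    """Apply one augmentation op to an H x W x 3 image in [0, 1]."""
    if op == "hflip":
        return image[:, ::-1].copy()
    if op == "vflip":
        return image[::-1].copy()
    if op == "rotation":
        return np.clip(
            _sk_rotate(image, params["angle"], mode="reflect", preserve_range=True), 0.0, 1.0
        )
    if op == "width_shift":
        dx = params["shift"] * image.shape[1]
        return np.clip(ndi.shift(image, (0.0, dx, 0.0), order=1, mode="reflect"), 0.0, 1.0)
    if op == "height_shift":
        dy = params["shift"] * image.shape[0]
        return np.clip(ndi.shift(image, (dy, 0.0, 0.0), order=1, mode="reflect"), 0.0, 1.0)
    raise ValueError(f"unknown augmentation op: {op}")


def execute_augmentation(image_set: LabeledImageSet, plan: AugmentationPlan) -> LabeledImageSet:
    """Append the planned augmented copies to ``image_set``.

    Source images are chosen round-robin within each class so no source is
    used more than ceil(generate / n_c) times; augmented items keep their
    source's label and are marked in provenance.
    """
    images = list(image_set.images)
    labels = list(image_set.labels)
    augmented_flags = [False] * len(images)
    for c, n_generate in sorted(plan.per_class_generate.items()):
        if n_generate == 0:
            continue
        class_idx = np.flatnonzero(image_set.labels == c)
        if len(class_idx) == 0:
            raise ValueError(f"cannot augment empty class {c}")
        ops = plan.assignments.get(c, [])
        if len(ops) != n_generate:
            raise ValueError(f"plan assignments for class {c} do not match generate count")
        for k, (op, params) in enumerate(ops):
            src = image_set.images[class_idx[k % len(class_idx)]]
            images.append(apply_augmentation_op(src, op, params))
            labels.append(c)
            augmented_flags.append(True)
    return LabeledImageSet(
        images=images,
        labels=np.asarray(labels),
        class_names=image_set.class_names,
        provenance={**image_set.provenance, "augmented_flags": augmented_flags},
    )


def class_weights(counts: dict[int, int], mode: str = "total") -> ClassWeights:
    """Inverse-frequency class weights for the weighted cross-entropy loss.

    mode "total" (default): w_i = (sum_c n_c) / n_i; mode "classes":
    w_i = K / n_i.  The two differ only by the constant factor (sum n)/K,
    which a learning rate absorbs.
    """
    if any(n <= 0 for n in counts.values()):
        raise ValueError("all class counts must be > 0")
    if mode == "total":
        scale = sum(counts.values())
    elif mode == "classes":
        scale = len(counts)
    else:
        raise ValueError(f"unknown mode: {mode}")
    return ClassWeights(w={c: scale / n for c, n in counts.items()})


def prevalence_ratios(counts: dict[int, int], digits: int = 2) -> dict[int, float]:
    """Per-class prevalence n_i / sum(n), rounded half-up to ``digits``."""
    if any(n < 0 for n in counts.values()):
        raise ValueError("counts must be >= 0")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("total count must be > 0")
    scale = 10**digits
    return {c: math.floor(n / total * scale + 0.5) / scale for c, n in counts.items()}
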