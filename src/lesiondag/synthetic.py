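"""Seeded synthetic inputs: lesion-like labeled images and simulated classifier outputs.

Everything downstream of image acquisition is testable without any download:
:func:`generate_dataset` draws lesion-like blobs on a skin-toned background
with class-dependent geometry and color plus a per-image multiplicative
illuminant tint (the von-Kries model the gray-world correction assumes), and
:func:`simulate_probabilities` draws per-classifier confidence matrices from a
Dirichlet concentrated on the true class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ClassBlobParams",
    "SyntheticImageSpec",
    "LabeledImageSet",
    "ProbabilitySimSpec",
    "default_class_params",
    "generate_lesion_image",
    "generate_dataset",
    "simulate_probabilities",
]


@dataclass(frozen=True)
class ClassBlobParams:
    """Blob descriptors for one lesion class.

    radius
        Mean blob radius in pixels.
    irregularity
        Amplitude of the sinusoidal boundary perturbation, relative to the
        radius, in [0, 1].
    color
        Base interior color, RGB in [0, 1].
    texture_sd
        Standard deviation of the interior pixel noise.
    """

    radius: float
    irregularity: float
    color: tuple[float, float, float]
    texture_sd: float


def default_class_params() -> tuple[ClassBlobParams, ...]:
    """Default three-class parameter set: melanoma-like (large, dark,
    irregular), nevus-like (small, brown, regular) and seborrheic-keratosis-like
    (mid-size, gray-brown, waxy)."""
    return (
        ClassBlobParams(radius=18.0, irregularity=0.45, color=(0.22, 0.10, 0.08), texture_sd=0.08),
        ClassBlobParams(radius=11.0, irregularity=0.10, color=(0.55, 0.33, 0.20), texture_sd=0.03),
        ClassBlobParams(radius=15.0, irregularity=0.25, color=(0.42, 0.34, 0.28), texture_sd=0.06),
    )


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Specification of a synthetic labeled image set.

    ``separability`` in [0, 1] scales the distance between class parameters:
    at 0 every class collapses onto the across-class mean (classes are
    indistinguishable), at 1 the classes keep their nominal parameters.
    ``illuminant_range`` gives per-channel multiplicative tint bounds; a tint
    is drawn uniformly per image and applied before clipping to [0, 1].
    """

    n_per_class: tuple[int, ...] = (50, 50, 50)
    image_size: tuple[int, int] = (64, 64)
    class_params: tuple[ClassBlobParams, ...] = field(default_factory=default_class_params)
    illuminant_range: tuple[tuple[float, float], ...] = ((0.8, 1.2), (0.8, 1.2), (0.8, 1.2))
    background_color: tuple[float, float, float] = (0.85, 0.72, 0.62)
    separability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_class) != len(self.class_params):
            raise ValueError("n_per_class and class_params must have equal length")
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("n_per_class entries must be >= 1")
        if self.image_size[0] < 32 or self.image_size[1] < 32:
            raise ValueError("image_size must be at least 32x32")
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must lie in [0, 1]")
        if len(self.illuminant_range) != 3:
            raise ValueError("illuminant_range needs one (lo, hi) pair per RGB channel")
        for lo, hi in self.illuminant_range:
            if lo < 0 or hi < lo:
                raise ValueError("illuminant bounds must satisfy 0 <= lo <= hi")

    @property
    def n_classes(self) -> int:
        return len(self.class_params)

    def effective_params(self, class_id: int) -> ClassBlobParams:
        """Class parameters after separability scaling toward the class mean."""
        params = self.class_params
        s = self.separability
        mean_radius = float(np.mean([p.radius for p in params]))
        mean_irr = float(np.mean([p.irregularity for p in params]))
        mean_color = np.mean([p.color for p in params], axis=0)
        mean_tex = float(np.mean([p.texture_sd for p in params]))
        p = params[class_id]
        return ClassBlobParams(
            radius=mean_radius + s * (p.radius - mean_radius),
            irregularity=mean_irr + s * (p.irregularity - mean_irr),
            color=tuple(mean_color + s * (np.asarray(p.color) - mean_color)),
            texture_sd=mean_tex + s * (p.texture_sd - mean_tex),
        )


@dataclass
class LabeledImageSet:
    """Images plus per-image labels and provenance.

    Images are H x W x 3 float arrays in [0, 1]; labels are class indices
    0..K-1 aligned with ``class_names``.
    """

    images: list[np.ndarray]
    labels: np.ndarray
    class_names: tuple[str, ...]
    provenance: dict

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must align")
        if len(self.labels) and self.labels.max() >= len(self.class_names):
            raise ValueError("label out of range for class_names")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, indices: np.ndarray) -> "LabeledImageSet":
        indices = np.asarray(indices, dtype=int)
        return LabeledImageSet(
            images=[self.images[i] for i in indices],
            labels=self.labels[indices],
            class_names=self.class_names,
            provenance={**self.provenance, "subset": True},
        )


@dataclass(frozen=True)
class ProbabilitySimSpec:
    """Simulated multiclass classifier outputs.

    Each of ``m`` classifiers emits, per sample, a Dirichlet draw with
    concentration 1 on off-classes and ``1 + fidelity`` on the true class;
    fidelity 0 gives chance-level classifiers, large fidelity near-oracles.
    """

    n: int
    K: int = 3
    m: int = 3
    fidelity: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.K < 2 or self.m < 1:
            raise ValueError("require n >= 1, K >= 2, m >= 1")
        if self.fidelity < 0:
            raise ValueError("fidelity must be >= 0")


def _image_seed(top_seed: int, class_id: int, index: int) -> int:
    # counter-based derivation: reproducible under any generation order
    ss = np.random.SeedSequence(entropy=top_seed, spawn_key=(class_id, index))
    return int(ss.generate_state(1)[0])


def generate_lesion_image(class_id: int, spec: SyntheticImageSpec, seed: int) -> np.ndarray:
    """Render one lesion-like image for ``class_id``.

    A radial blob with sinusoidal boundary perturbation is anti-aliased onto
    the background, interior texture noise added, then the per-image
    illuminant tint applied multiplicatively and the result clipped to [0, 1].
    Identical (class_id, spec, seed) yields a bit-identical image.
    """
    if not 0 <= class_id < spec.n_classes:
        raise IndexError(f"class_id {class_id} out of range for {spec.n_classes} classes")
    rng = np.random.default_rng(seed)
    h, w = spec.image_size
    p = spec.effective_params(class_id)

    radius = p.radius * (1.0 + 0.1 * rng.standard_normal())
    n_lobes = int(rng.integers(3, 8))
    phase = rng.uniform(0.0, 2.0 * np.pi)
    cy = h / 2.0 + rng.uniform(-1.0, 1.0)
    cx = w / 2.0 + rng.uniform(-1.0, 1.0)

    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    boundary = radius * (1.0 + p.irregularity * 0.5 * np.sin(n_lobes * theta + phase))
    # 1-px smoothstep anti-aliasing across the boundary
    alpha = np.clip(boundary - dist + 0.5, 0.0, 1.0)

    background = np.asarray(spec.background_color, dtype=float)
    color = np.asarray(p.color, dtype=float)
    image = background[None, None, :] + alpha[:, :, None] * (color - background)[None, None, :]
    noise = rng.standard_normal((h, w, 3)) * p.texture_sd
    image = image + alpha[:, :, None] * noise
    image = np.clip(image, 0.0, 1.0)

    tint = np.array([rng.uniform(lo, hi) for lo, hi in spec.illuminant_range])
    return np.clip(image * tint[None, None, :], 0.0, 1.0)


def generate_dataset(
    spec: SyntheticImageSpec, class_names: tuple[str, ...] | None = None
) -> LabeledImageSet:
    """Generate ``n_per_class[c]`` images per class ``c`` under ``spec``."""
    if class_names is None:
        class_names = tuple(f"class{c}" for c in range(spec.n_classes))
    images: list[np.ndarray] = []
    labels: list[int] = []
    for c, n in enumerate(spec.n_per_class):
        for i in range(n):
            images.append(generate_lesion_image(c, spec, _image_seed(spec.seed, c, i)))
            labels.append(c)
    return LabeledImageSet(
        images=images,
        labels=np.asarray(labels),
        class_names=class_names,
        provenance={"source": "synthetic", "seed": spec.seed},
    )


def simulate_probabilities(
    spec: ProbabilitySimSpec, true_labels: np.ndarray
) -> list[np.ndarray]:
    """Simulate ``m`` classifier probability matrices over the same samples.

    Returns a list of m arrays of shape (n, K); every row is a Dirichlet draw
    with concentration ``1 + fidelity`` on the sample's true class and 1
    elsewhere, so each row sums to 1.
    """
    true_labels = np.asarray(true_labels, dtype=int)
    if len(true_labels) != spec.n:
        raise ValueError("true_labels length must equal spec.n")
    if len(true_labels) and (true_labels.min() < 0 or true_labels.max() >= spec.K):
        raise ValueError("labels out of range")
    alpha = np.ones((spec.n, spec.K))
    alpha[np.arange(spec.n), true_labels] += spec.fidelity
    matrices = []
    for j in range(spec.m):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(j,))
        )
        gamma = rng.gamma(shape=alpha)  # Dirichlet via normalized gammas
        matrices.append(gamma / gamma.sum(axis=1, keepdims=True))
    return matrices
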