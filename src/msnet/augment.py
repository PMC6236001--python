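"""Five-transform data augmentation for the training branch.

Each original training image yields 150 derived images under the default
configuration: 30 rotations (-30..30 deg in steps of 2, identity excluded),
30 rescalings (0.7..1.3 in steps of 0.02, identity excluded), 30 Gaussian
noise injections (zero mean, variance 0.01), 30 random integer translations
(per-axis magnitude uniform on [0, 15] pixels with independent random sign),
and 30 gamma corrections (0.4..1.6 in steps of 0.04, identity excluded).
Together with the original that multiplies the training set by 151.

Geometric transforms use bilinear interpolation with zero fill (zeros match
the dark MRI background); all outputs keep the input shape and stay in
[0, 1].  Augmentation is applied to the training set only, never to test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktransform

from . import errors
from .preprocess import ImageDataset, LabeledImage


def _grid(start: float, stop: float, step: float, exclude: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step)) + 1
    vals = [round(start + k * step, 10) for k in range(n)]
    return tuple(v for v in vals if v != exclude)


@dataclass(frozen=True)
class AugmentConfig:
    """Parameter grids and draw counts of the five augmentation operators."""

    rotation_angles: tuple[float, ...] = _grid(-30.0, 30.0, 2.0, exclude=0.0)
    scale_factors: tuple[float, ...] = _grid(0.7, 1.3, 0.02, exclude=1.0)
    noise_variance: float = 0.01
    noise_count: int = 30
    translation_max: int = 15
    translation_count: int = 30
    gamma_values: tuple[float, ...] = _grid(0.4, 1.6, 0.04, exclude=1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_count < 0 or self.translation_count < 0:
            raise ValueError("draw counts must be non-negative")
        if 0.0 in self.rotation_angles or 1.0 in self.scale_factors or 1.0 in self.gamma_values:
            raise ValueError("parameter grids must not contain the identity value")

    @property
    def per_image_count(self) -> int:
        return (
            len(self.rotation_angles)
            + len(self.scale_factors)
            + self.noise_count
            + self.translation_count
            + len(self.gamma_values)
        )


def rotate(image: np.ndarray, angle: float) -> np.ndarray:
    """Rotate about the image center (degrees, bilinear, zero fill)."""
    if not np.isfinite(angle):
        raise ValueError("angle must be finite")
    if angle == 0:
        return np.array(image, dtype=np.float64)
    return sktransform.rotate(
        np.asarray(image, dtype=np.float64), angle, order=1, mode="constant", cval=0.0
    )


def rescale(image: np.ndarray, factor: float) -> np.ndarray:
    """Isotropic zoom about the center, cropped/padded back to the input shape."""
    if factor <= 0:
        raise errors.NonPositiveFactor(f"scale factor must be > 0, got {factor}")
    image = np.asarray(image, dtype=np.float64)
    if factor == 1.0:
        return image.copy()
    zoomed = sktransform.rescale(
        image, factor, order=1, mode="constant", cval=0.0, anti_aliasing=False
    )
    return _fit_to_shape(zoomed, image.shape)


def _fit_to_shape(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Center-crop or zero-pad each axis to the requested shape."""
    out = img
    for axis in (0, 1):
        have, want = out.shape[axis], shape[axis]
        if have > want:
            start = (have - want) // 2
            out = out.take(range(start, start + want), axis=axis)
        elif have < want:
            before = (want - have) // 2
            pad = [(0, 0), (0, 0)]
            pad[axis] = (before, want - have - before)
            out = np.pad(out, pad, mode="constant")
    return out


def add_noise(image: np.ndarray, variance: float, rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise, clipping the result to [0, 1]."""
    if variance < 0:
        raise errors.NegativeVariance(f"variance must be >= 0, got {variance}")
    image = np.asarray(image, dtype=np.float64)
    if variance == 0:
        return image.copy()
    noisy = image + rng.normal(0.0, np.sqrt(variance), size=image.shape)
    return np.clip(noisy, 0.0, 1.0)


def translate(image: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Integer-pixel shift by (dx columns, dy rows) with zero fill."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    if abs(dx) >= w or abs(dy) >= h:
        return np.zeros_like(image)
    out = np.zeros_like(image)
    src_r = slice(max(0, -dy), min(h, h - dy))
    src_c = slice(max(0, -dx), min(w, w - dx))
    dst_r = slice(max(0, dy), min(h, h + dy))
    dst_c = slice(max(0, dx), min(w, w + dx))
    out[dst_r, dst_c] = image[src_r, src_c]
    return out


def gamma_correct(image: np.ndarray, gamma: float) -> np.ndarray:
    """Elementwise power transform ``phi ** gamma``; 0 and 1 are fixed points."""
    if gamma <= 0:
        raise errors.NonPositiveGamma(f"gamma must be > 0, got {gamma}")
    return np.power(np.asarray(image, dtype=np.float64), gamma)


def augment_image(
    image: np.ndarray, config: AugmentConfig, rng: np.random.Generator
) -> list[tuple[str, np.ndarray]]:
    """Produce all derived images for one original, tagged with provenance.

    Returns ``(tag, image)`` pairs in a fixed order: rotation grid, scale
    grid, noise draws, translation draws, gamma grid.  The tag encodes the
    transform and its parameter (e.g. ``rot-30``, ``trans04:+3-7``).
    """
    out: list[tuple[str, np.ndarray]] = []
    for a in config.rotation_angles:
        out.append((f"rot{a:+g}", rotate(image, a)))
    for s in config.scale_factors:
        out.append((f"scale{s:g}", rescale(image, s)))
    for k in range(config.noise_count):
        out.append((f"noise{k:02d}", add_noise(image, config.noise_variance, rng)))
    for k in range(config.translation_count):
        mag = rng.integers(0, config.translation_max + 1, size=2)
        sign = rng.choice([-1, 1], size=2)
        dx, dy = int(mag[0] * sign[0]), int(mag[1] * sign[1])
        out.append((f"trans{k:02d}:{dx:+d}{dy:+d}", translate(image, dx, dy)))
    for g in config.gamma_values:
        out.append((f"gamma{g:g}", gamma_correct(image, g)))
    return out


def augment_training_set(train: ImageDataset, config: AugmentConfig) -> ImageDataset:
    """Expand a training set with every original plus its derived images.

    With the default configuration the result is 151x the input size.
    Derived sample ids encode parent, transform and parameter; labels are
    inherited from the parent.
    """
    if len(train) == 0:
        raise errors.EmptySource("training set is empty")
    rng = np.random.default_rng(config.seed)
    items: list[LabeledImage] = []
    for it in train:
        items.append(it)
        for tag, img in augment_image(it.image, config, rng):
            items.append(
                LabeledImage(
                    image=img,
                    label=it.label,
                    source_id=it.source_id,
                    sample_id=f"{it.sample_id}|{tag}",
                )
            )
    return ImageDataset(items)
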