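"""Synthetic brain-slice phantoms: plaque-bearing "MS" vs plaque-free "HC".

Each phantom is a centered ellipse of textured tissue (smoothed Gaussian
noise) over a dark background.  MS slices additionally carry a small number
of hyperintense Gaussian blobs ("plaques") at random positions inside the
ellipse — the class-discriminating feature, mirroring the bright
demyelinated lesions of real FLAIR/T2 slices.  ``plaque_contrast`` is the
separability knob: at 0 the two classes are identically distributed.

The two classes are drawn through different "virtual scanners": each class
applies its own affine intensity transform (gain and offset) after
observation noise, so the per-image histogram stretch of the preprocessing
stage has a real inter-source matching job to do — and can do it exactly.

Everything is seeded and deterministic; no anatomical realism is attempted
beyond what the pipeline needs (dynamic range, a dark background for the
zero-fill of geometric augmentation, and a localized class signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from . import errors
from .preprocess import HC, MS, ImageDataset, LabeledImage


@dataclass(frozen=True)
class SynthParams:
    """Phantom geometry and intensity parameters (intensities in [0, 1])."""

    image_side: int = 256
    brain_axes: tuple[float, float] | None = None      # semi-axes (rows, cols)
    tissue_mean: float = 0.55
    tissue_sd: float = 0.18
    texture_smoothing: float = 3.0                     # Gaussian sigma, pixels
    plaque_count_range: tuple[int, int] = (1, 4)
    plaque_radius_range: tuple[float, float] | None = None
    plaque_contrast: float = 0.35
    background_level: float = 0.05
    noise_sd: float = 0.02
    #: per-class (gain, offset) of the two virtual scanners
    scanner_gain: dict = field(
        default_factory=lambda: {MS: (0.85, 0.05), HC: (0.65, 0.20)}
    )
    seed: int = 0

    def resolved_axes(self) -> tuple[float, float]:
        if self.brain_axes is not None:
            return self.brain_axes
        return (0.42 * self.image_side, 0.34 * self.image_side)

    def resolved_radii(self) -> tuple[float, float]:
        if self.plaque_radius_range is not None:
            return self.plaque_radius_range
        return (max(2.0, 0.015 * self.image_side), max(3.0, 0.035 * self.image_side))

    def validate(self) -> None:
        if self.image_side < 8:
            raise errors.InvalidParams("image_side must be >= 8")
        if self.plaque_contrast < 0:
            raise errors.InvalidParams("plaque_contrast must be >= 0")
        lo, hi = self.plaque_count_range
        if lo < 0 or hi < lo:
            raise errors.InvalidParams("plaque_count_range must be 0 <= lo <= hi")
        rlo, rhi = self.resolved_radii()
        if rlo <= 0 or rhi < rlo or rhi >= min(self.resolved_axes()):
            raise errors.InvalidParams("plaque radii must be positive and smaller "
                                       "than the brain semi-axes")


def generate_slice(params: SynthParams, label: str,
                   rng: np.random.Generator) -> tuple[LabeledImage, list[dict]]:
    """One phantom slice plus the ground-truth plaque provenance.

    Returns ``(labeled_image, plaques)`` where ``plaques`` is a list of
    ``{"row", "col", "radius"}`` dicts (empty for HC).
    """
    params.validate()
    if label not in (MS, HC):
        raise ValueError(f"label must be {MS} or {HC}")
    side = params.image_side
    ay, ax = params.resolved_axes()
    cy = cx = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    inside = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    texture = gaussian_filter(rng.normal(0.0, params.tissue_sd, (side, side)),
                              params.texture_smoothing)
    img = np.where(inside, params.tissue_mean + texture, params.background_level)

    plaques: list[dict] = []
    if label == MS:
        lo, hi = params.plaque_count_range
        k = int(rng.integers(lo, hi + 1))
        rlo, rhi = params.resolved_radii()
        for _ in range(k):
            # uniform position inside a slightly shrunken ellipse
            t = rng.uniform(0, 2 * np.pi)
            r = np.sqrt(rng.uniform())
            py = cy + 0.85 * ay * r * np.sin(t)
            px = cx + 0.85 * ax * r * np.cos(t)
            radius = rng.uniform(rlo, rhi)
            blob = np.exp(-(((yy - py) ** 2 + (xx - px) ** 2) / (2 * (radius / 2) ** 2)))
            img = img + params.plaque_contrast * blob * inside
            plaques.append({"row": float(py), "col": float(px), "radius": float(radius)})

    # observation noise precedes the scanner transform so that per-image
    # histogram stretching can cancel the scanner's (gain, offset) exactly:
    # the class signal must live in the plaques, not in the noise scale
    img = np.clip(img + rng.normal(0.0, params.noise_sd, img.shape), 0.0, 1.0)
    gain, offset = params.scanner_gain[label]
    img = np.clip(gain * img + offset, 0.0, 1.0)
    sample_id = f"{label}_{rng.integers(0, 2**32):08x}"
    return (
        LabeledImage(image=img, label=label, source_id=f"synth-scanner-{label}",
                     sample_id=sample_id),
        plaques,
    )


def generate_dataset(params: SynthParams, n_ms: int = 676, n_hc: int = 681,
                     seed: int | None = None) -> tuple[ImageDataset, list[dict]]:
    """A full two-class phantom dataset with per-slice provenance.

    Default class sizes mirror the reference clinical dataset (676 MS / 681 HC slices).
    Each slice gets its own child seed derived from ``seed`` (falling back
    to ``params.seed``), so the dataset is reproducible and individual
    slices are independent.

    Returns ``(dataset, provenance)`` where provenance holds one record per
    slice: sample_id, label and the ground-truth plaque list.
    """
    if n_ms < 0 or n_hc < 0:
        raise ValueError("class counts must be >= 0")
    params.validate()
    master = np.random.SeedSequence(params.seed if seed is None else seed)
    labels = [MS] * n_ms + [HC] * n_hc
    items: list[LabeledImage] = []
    provenance: list[dict] = []
    for i, (label, child) in enumerate(zip(labels, master.spawn(len(labels)))):
        rng = np.random.default_rng(child)
        item, plaques = generate_slice(params, label, rng)
        item = LabeledImage(item.image, item.label, item.source_id,
                            sample_id=f"{label}_{i:04d}")
        items.append(item)
        provenance.append({"sample_id": item.sample_id, "label": label,
                           "plaques": plaques})
    return ImageDataset(items), provenance
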