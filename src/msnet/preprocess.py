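"""Contrast normalization and dataset assembly.

Brain slices arrive from two different scanners/sources with unrelated
intensity scales.  Histogram stretching linearly rescales each image so its
own minimum maps to 0 and its maximum to 1, matching the dynamic range of
the two sources before they are pooled into one labeled dataset.  A seeded
hold-out split then partitions the dataset per class into train and test.

A *GrayImage* throughout this package is a plain 2-D ``float64`` numpy array
of intensities; after normalization all values lie in [0, 1].
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import errors

MS = "MS"
HC = "HC"
CLASSES = (HC, MS)  # index 1 (MS) is the positive class


@dataclass(frozen=True)
class LabeledImage:
    """A single grayscale slice with its class label and provenance."""

    image: np.ndarray
    label: str
    source_id: str
    sample_id: str

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")


class ImageDataset:
    """An ordered collection of :class:`LabeledImage` with unique sample ids."""

    def __init__(self, items: Sequence[LabeledImage]):
        self.items = list(items)
        ids = [it.sample_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_id values must be unique within a dataset")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for it in self.items:
            counts[it.label] += 1
        return counts

    def subset(self, label: str) -> list[LabeledImage]:
        return [it for it in self.items if it.label == label]

    def sample_ids(self) -> set[str]:
        return {it.sample_id for it in self.items}

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack into ``(X, y)`` with X of shape (N, 1, H, W) and y in {0, 1}.

        y uses the class index in :data:`CLASSES` (MS = 1, the positive class).
        """
        X = np.stack([it.image for it in self.items])[:, None, :, :]
        y = np.array([CLASSES.index(it.label) for it in self.items], dtype=np.int64)
        return X.astype(np.float64), y


@dataclass(frozen=True)
class HoldoutSpec:
    """Per-class train/test counts and the seed of the random split."""

    train_per_class: Mapping[str, int]
    test_per_class: Mapping[str, int]
    seed: int = 0

    def __post_init__(self) -> None:
        for m in (self.train_per_class, self.test_per_class):
            if any(v < 0 for v in m.values()):
                raise ValueError("hold-out counts must be non-negative")


#: The reference hold-out setting: 350/350 train, 326/331 test per class.
DEFAULT_HOLDOUT = HoldoutSpec(
    train_per_class={MS: 350, HC: 350}, test_per_class={MS: 326, HC: 331}
)


def histogram_stretch(image: np.ndarray) -> np.ndarray:
    """Linearly rescale intensities so the image spans exactly [0, 1].

    phi(x, y) = (mu(x, y) - mu_min) / (mu_max - mu_min), where mu_min and
    mu_max are the minimum and maximum intensity of this image alone.

    Raises
    ------
    DegenerateRange
        If the image is constant (mu_max == mu_min).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("image must be non-empty")
    lo = image.min()
    hi = image.max()
    if hi == lo:
        raise errors.DegenerateRange("constant image: histogram stretch undefined")
    return (image - lo) / (hi - lo)


def decode_to_float(raw: np.ndarray) -> np.ndarray:
    """Map an integer-typed image to floats in [0, 1] by its dtype maximum."""
    raw = np.asarray(raw)
    if np.issubdtype(raw.dtype, np.integer):
        return raw.astype(np.float64) / np.iinfo(raw.dtype).max
    return raw.astype(np.float64)


def assemble_dataset(
    ms_images: Iterable[np.ndarray],
    hc_images: Iterable[np.ndarray],
    ms_source: str = "ms-source",
    hc_source: str = "hc-source",
) -> ImageDataset:
    """Normalize each image and merge both sources into one labeled dataset.

    Histogram stretching is applied per image (it is idempotent, so already
    normalized inputs pass through unchanged).  Labels are assigned by source
    collection and sample ids are generated as ``MS_0000``, ``HC_0000``, ...

    Raises
    ------
    EmptySource
        If either collection is empty.
    """
    ms_images = list(ms_images)
    hc_images = list(hc_images)
    if not ms_images or not hc_images:
        raise errors.EmptySource("both the MS and HC collections must be non-empty")
    items = []
    for label, source, imgs in ((MS, ms_source, ms_images), (HC, hc_source, hc_images)):
        for i, img in enumerate(imgs):
            items.append(
                LabeledImage(
                    image=histogram_stretch(img),
                    label=label,
                    source_id=source,
                    sample_id=f"{label}_{i:04d}",
                )
            )
    return ImageDataset(items)


def normalize_dataset(dataset: ImageDataset) -> ImageDataset:
    """Apply histogram stretching to every image of an existing dataset."""
    return ImageDataset(
        [
            LabeledImage(histogram_stretch(it.image), it.label, it.source_id, it.sample_id)
            for it in dataset
        ]
    )


def holdout_split(
    dataset: ImageDataset, spec: HoldoutSpec
) -> tuple[ImageDataset, ImageDataset]:
    """Seeded per-class random hold-out partition.

    Each class is independently permuted with a generator seeded from
    ``spec.seed``; the first ``train_per_class[c]`` images go to the training
    set and the next ``test_per_class[c]`` to the test set.  Any leftover
    images of an undersubscribed class are dropped from both sets.

    Raises
    ------
    InsufficientSamples
        If a class has fewer images than train + test requested.
    """
    rng = np.random.default_rng(spec.seed)
    train_items: list[LabeledImage] = []
    test_items: list[LabeledImage] = []
    for label in CLASSES:
        pool = dataset.subset(label)
        n_train = spec.train_per_class.get(label, 0)
        n_test = spec.test_per_class.get(label, 0)
        if n_train + n_test > len(pool):
            raise errors.InsufficientSamples(
                f"class {label}: requested {n_train}+{n_test} of {len(pool)} available"
            )
        order = rng.permutation(len(pool))
        train_items.extend(pool[i] for i in order[:n_train])
        test_items.extend(pool[i] for i in order[n_train : n_train + n_test])
    return ImageDataset(train_items), ImageDataset(test_items)


# --- file I/O --------------------------------------------------------------

def read_image(path: str | Path, nifti_slice: int | None = None) -> np.ndarray:
    """Read one grayscale slice from PNG/TIFF or a single-slice NIfTI.

    Integer images are mapped to [0, 1] by their dtype maximum; multichannel
    images are averaged to one channel.  For ``.nii``/``.nii.gz`` inputs,
    ``nifti_slice`` selects the axial slice (defaults to the middle one).
    """
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
        if vol.ndim == 2:
            return vol
        if nifti_slice is None:
            nifti_slice = vol.shape[-1] // 2
        return vol[..., nifti_slice]
    import imageio.v3 as iio

    raw = iio.imread(path)
    if raw.ndim == 3:
        raw = raw.mean(axis=-1).astype(raw.dtype)
    return decode_to_float(raw)


def load_directory(
    directory: str | Path, pattern: str = "*.png", nifti_slice: int | None = None
) -> list[np.ndarray]:
    """Read every image matching ``pattern`` in a directory, sorted by name."""
    directory = Path(directory)
    return [read_image(p, nifti_slice) for p in sorted(directory.glob(pattern))]


def write_dataset(dataset: ImageDataset, out_dir: str | Path) -> Path:
    """Write images as 8-bit PNGs plus a CSV manifest; returns the manifest path."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "label", "source_id", "path"])
        for it in dataset:
            fname = f"{it.sample_id}.png"
            png = np.clip(np.rint(it.image * 255), 0, 255).astype(np.uint8)
            iio.imwrite(out_dir / fname, png)
            writer.writerow([it.sample_id, it.label, it.source_id, fname])
    return manifest


def read_manifest_dataset(manifest: str | Path) -> ImageDataset:
    """Load a dataset previously written by :func:`write_dataset`."""
    manifest = Path(manifest)
    base = manifest.parent
    items = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            items.append(
                LabeledImage(
                    image=read_image(base / row["path"]),
                    label=row["label"],
                    source_id=row["source_id"],
                    sample_id=row["sample_id"],
                )
            )
    return ImageDataset(items)
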