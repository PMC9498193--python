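"""Pre-processing: raw volume/label pairs to the slice-wise training array.

The pipeline mirrors standard practice for slice-wise (2.5D) segmentation:
cases are split at the volume level, each slice stack is resampled in-plane
to ``m x m`` (bicubic for images, nearest-neighbour for labels), intensities
are min-max normalised to [0, 255] with statistics shared across the whole
training cohort, the target structure is binarised (cartilage and other
bones discarded), small labelling artefacts are removed by a per-slice
morphological opening, and everything is stacked into one slice dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .io import ImageVolume, LabelVolume

__all__ = [
    "SliceDataset",
    "split_cases",
    "resample_slice_stack",
    "resample_labels",
    "normalize_cohort",
    "binarize_bone",
    "clean_labels",
    "build_slice_dataset",
]

logger = logging.getLogger(__name__)


@dataclass
class SliceDataset:
    """Stacked 2D training pairs.

    ``images`` is ``(S, m, m)`` float32 in [0, 255]; ``masks`` is
    ``(S, m, m)`` uint8 binary; ``provenance`` records ``(case_id,
    slice_index)`` per entry.
    """

    images: np.ndarray
    masks: np.ndarray
    provenance: list

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.masks = np.asarray(self.masks, dtype=np.uint8)
        if self.images.ndim != 3 or self.images.shape != self.masks.shape:
            raise ValueError("images and masks must both be (S, m, m) and aligned")
        if self.images.shape[1] != self.images.shape[2]:
            raise ValueError("slices must be square (m x m)")
        if len(self.provenance) != len(self.images):
            raise ValueError("provenance length must equal the slice count")
        if self.images.size and (self.images.min() < 0 or self.images.max() > 255):
            raise ValueError("image values must lie in [0, 255]")
        if not np.isin(self.masks, (0, 1)).all():
            raise ValueError("mask values must be binary")

    @property
    def n_slices(self) -> int:
        return len(self.images)

    @property
    def m(self) -> int:
        return self.images.shape[1]

    def subset(self, indices) -> "SliceDataset":
        idx = np.asarray(indices)
        return SliceDataset(
            images=self.images[idx],
            masks=self.masks[idx],
            provenance=[self.provenance[i] for i in idx],
        )


def split_cases(case_ids: list, train_fraction: float, seed: int) -> tuple[list, list]:
    """Randomly partition case ids into disjoint train/test sets.

    The split is at case level (never slice level, which would leak adjacent
    slices of one knee across the split).  ``round(n * train_fraction)``
    cases go to training; reproducible under ``seed``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    ids = list(case_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 cases to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(len(ids) * train_fraction))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train = sorted(ids[i] for i in order[:n_train])
    test = sorted(ids[i] for i in order[n_train:])
    return train, test


def resample_slice_stack(volume: ImageVolume, m: int = 128) -> ImageVolume:
    """Resample every slice independently to ``m x m`` by bicubic interpolation.

    The slice count is untouched; in-plane spacing is rescaled so the
    physical extent of each slice is preserved.
    """
    if m < 8:
        raise ValueError("m must be >= 8")
    n_s, n_r, n_c = volume.shape
    zoom = (1.0, m / n_r, m / n_c)
    out = ndimage.zoom(
        np.asarray(volume.voxels, dtype=float), zoom, order=3, mode="mirror", grid_mode=True
    )
    new_spacing = volume.spacing_mm * np.array([1.0, n_r / m, n_c / m])
    return ImageVolume(voxels=out, spacing_mm=new_spacing, origin_mm=volume.origin_mm)


def resample_labels(labels: LabelVolume, m: int = 128) -> LabelVolume:
    """Nearest-neighbour in-plane resampling; labels stay integral."""
    if m < 8:
        raise ValueError("m must be >= 8")
    n_s, n_r, n_c = labels.shape
    zoom = (1.0, m / n_r, m / n_c)
    out = ndimage.zoom(labels.labels, zoom, order=0, mode="nearest", grid_mode=True)
    new_spacing = labels.spacing_mm * np.array([1.0, n_r / m, n_c / m])
    return LabelVolume(
        labels=out,
        spacing_mm=new_spacing,
        origin_mm=labels.origin_mm,
        label_codes=labels.label_codes,
    )


def normalize_cohort(volumes: list[ImageVolume]) -> list[ImageVolume]:
    """Min-max normalise a cohort to [0, 255] with ONE shared min/max.

    The statistics are pooled over every volume in the list (the training
    cohort), so relative intensity differences between scanners survive
    normalisation.  Output voxels are floats.
    """
    if not volumes:
        raise ValueError("need at least one volume")
    gmin = min(float(v.voxels.min()) for v in volumes)
    gmax = max(float(v.voxels.max()) for v in volumes)
    if gmax <= gmin:
        raise ValueError("cohort is constant (max == min); cannot normalise")
    scale = 255.0 / (gmax - gmin)
    return [v.with_voxels((np.asarray(v.voxels, dtype=float) - gmin) * scale) for v in volumes]


def cohort_min_max(volumes: list[ImageVolume]) -> tuple[float, float]:
    """The shared statistics ``normalize_cohort`` would use (for manifests)."""
    if not volumes:
        raise ValueError("need at least one volume")
    return (
        min(float(v.voxels.min()) for v in volumes),
        max(float(v.voxels.max()) for v in volumes),
    )


def binarize_bone(labels: LabelVolume, bone: str) -> LabelVolume:
    """1 where the named bone's code occurs, 0 elsewhere.

    Cartilage and all other structures are discarded: one binary target per
    bone is trained.  An absent bone yields an all-zero mask (logged, not an
    error — phantoms and partial scans may omit structures).
    """
    code = labels.code(bone)  # raises KeyError for unknown names
    mask = (labels.labels == code).astype(np.uint8)
    if not mask.any():
        logger.warning("bone %r (code %d) absent from volume; mask is empty", bone, code)
    return LabelVolume(
        labels=mask,
        spacing_mm=labels.spacing_mm,
        origin_mm=labels.origin_mm,
        label_codes={"background": 0, bone: 1},
    )


def clean_labels(mask: LabelVolume, radius_vox: int = 1) -> LabelVolume:
    """Per-slice 2D morphological opening with a disc structuring element.

    Removes isolated one-pixel label regions that disturb training while
    leaving large structures essentially unchanged; the result is always a
    subset of the input's dilation (opening is anti-extensive followed by
    a dilation bounded by the original support).
    """
    if radius_vox < 1:
        raise ValueError("radius_vox must be >= 1")
    selem = disk(radius_vox)
    src = mask.labels.astype(bool)
    out = np.empty_like(src)
    for i in range(src.shape[0]):
        out[i] = ndimage.binary_opening(src[i], structure=selem)
    return replace(mask, labels=out.astype(mask.labels.dtype))


def build_slice_dataset(
    volumes: list[ImageVolume],
    masks: list[LabelVolume],
    case_ids: list | None = None,
) -> SliceDataset:
    """Stack normalised image slices with their binary mask slices.

    ``volumes`` must already be normalised to [0, 255] and resampled to a
    common square in-plane size; ``masks`` must be binary and aligned
    shape-for-shape with their volumes.  The total entry count S equals the
    summed slice counts, and provenance records each slice's origin.
    """
    if len(volumes) != len(masks):
        raise ValueError("volumes and masks must pair up one-to-one")
    if case_ids is None:
        case_ids = [f"case{i:03d}" for i in range(len(volumes))]
    images, targets, provenance = [], [], []
    for cid, vol, lab in zip(case_ids, volumes, masks):
        if vol.shape != lab.shape:
            raise ValueError(
                f"case {cid}: image shape {vol.shape} != mask shape {lab.shape}"
            )
        images.append(np.asarray(vol.voxels, dtype=np.float32))
        targets.append((lab.labels > 0).astype(np.uint8))
        provenance.extend((cid, s) for s in range(vol.shape[0]))
    return SliceDataset(
        images=np.concatenate(images, axis=0),
        masks=np.concatenate(targets, axis=0),
        provenance=provenance,
    )
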