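"""Surface detection and preparation of B-scans for the classifier.

The network consumes images ``X`` of shape ``target x target x 3`` (512 at
full scale): the axial dimension is cropped to the signal-bearing top half,
the lateral dimension resampled, intensities min-max normalized to [0, 1] per
image, and the single channel replicated three times.

Surface detection is threshold-based: per A-line, the first axial index whose
(depth-median-smoothed) intensity exceeds the background mean plus ``k``
background standard deviations, followed by a median filter across A-lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

from .phantom import Cohort, OCTVolume


class SurfaceDetectionError(RuntimeError):
    """Raised when too few A-lines yield a usable surface estimate."""


@dataclass
class SurfaceMap:
    """Per-A-line axial index of the skin surface."""

    surface_index: np.ndarray  # (lateral,) int
    quality: np.ndarray  # (lateral,) bool, True where the crossing was found

    def __post_init__(self) -> None:
        if self.surface_index.shape != self.quality.shape:
            raise ValueError("surface_index and quality must align")

    @property
    def n_usable(self) -> int:
        return int(self.quality.sum())


@dataclass
class PreparedImage:
    """Normalized network input X with provenance and label."""

    pixels: np.ndarray  # (target, target, 3) float32 in [0, 1]
    source: tuple[str, int, int]  # (subject_id, week, slice_index)
    label: int

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be (H, W, 3)")
        if self.label not in (0, 1):
            raise ValueError("label must be binary")


def detect_surface(bscan: np.ndarray, k: float = 3.0, median_window: int = 15,
                   background_rows: int | None = None,
                   max_unusable_frac: float = 0.5) -> SurfaceMap:
    """Locate the skin surface on every A-line of a B-scan.

    Background statistics come from the top ``background_rows`` rows (default
    ``max(4, depth // 32)``), assumed to lie above the tissue.  A small
    depth-wise median filter (width 3) suppresses isolated noise spikes
    without shifting step edges, so a noiseless flat surface at row ``r`` is
    detected exactly at ``r``.
    """
    bscan = np.asarray(bscan, dtype=float)
    if bscan.ndim != 2:
        raise ValueError("bscan must be 2-D (depth, lateral)")
    if not np.all(np.isfinite(bscan)) or np.any(bscan < 0):
        raise ValueError("bscan must be finite and non-negative")
    depth, lateral = bscan.shape
    if background_rows is None:
        background_rows = max(4, depth // 32)
    bg = bscan[:background_rows]
    threshold = bg.mean() + k * bg.std()

    smoothed = ndimage.median_filter(bscan, size=(3, 1), mode="nearest")
    above = smoothed > threshold
    quality = above.any(axis=0)
    first = np.where(quality, above.argmax(axis=0), 0)
    if quality.sum() < (1.0 - max_unusable_frac) * lateral:
        raise SurfaceDetectionError(
            f"surface found on only {int(quality.sum())}/{lateral} A-lines")
    # fill unusable A-lines with the median of usable ones before smoothing
    fill = int(np.median(first[quality]))
    filled = np.where(quality, first, fill)
    surface = ndimage.median_filter(filled, size=median_window, mode="nearest")
    return SurfaceMap(surface_index=surface.astype(int), quality=quality)


def prepare_image(bscan: np.ndarray, source: tuple[str, int, int] = ("", 0, 0),
                  label: int = 0, target: int = 512, crop_rows: int | None = 512,
                  crop_offset: int = 0) -> PreparedImage:
    """Map a raw B-scan to the network input.

    Axial crop keeps rows ``[crop_offset, crop_offset + crop_rows)`` (the top
    512 of 1024 at full scale, where the OCT signal lives); both axes are then
    resampled to ``target`` with anti-aliased linear interpolation; intensities
    are min-max normalized per image (a constant image maps to all zeros); the
    channel is replicated three times.
    """
    bscan = np.asarray(bscan, dtype=float)
    if bscan.ndim != 2:
        raise ValueError("bscan must be 2-D (depth, lateral)")
    depth = bscan.shape[0]
    if crop_rows is None:
        crop_rows = depth
    top = min(crop_offset + crop_rows, depth)
    cropped = bscan[crop_offset:top]
    if cropped.shape == (target, target):
        resampled = cropped.astype(float)
    else:
        resampled = resize(cropped, (target, target), order=1,
                           anti_aliasing=True, preserve_range=True)
    lo, hi = float(resampled.min()), float(resampled.max())
    if hi > lo:
        norm = (resampled - lo) / (hi - lo)
    else:
        norm = np.zeros_like(resampled)
    pixels = np.repeat(norm[:, :, None], 3, axis=2).astype(np.float32)
    return PreparedImage(pixels=pixels, source=source, label=int(label))


def prepare_mask(mask: np.ndarray, target: int = 512, crop_rows: int | None = 512,
                 crop_offset: int = 0) -> np.ndarray:
    """Apply the prepare_image geometry (crop + resize) to a boolean mask."""
    mask = np.asarray(mask, dtype=float)
    depth = mask.shape[0]
    if crop_rows is None:
        crop_rows = depth
    top = min(crop_offset + crop_rows, depth)
    cropped = mask[crop_offset:top]
    resampled = resize(cropped, (target, target), order=0, preserve_range=True)
    return resampled > 0.5


@dataclass
class ImageDataset:
    """In-memory stack of prepared images plus their index table.

    ``index`` columns: subject_id, group, week, slice, label, lesion (ground
    truth per-slice flag when available).  Row ``i`` of ``index`` describes
    ``images[i]``.
    """

    images: np.ndarray  # (n, target, target, 3) float32
    index: pd.DataFrame
    masks: np.ndarray | None = None  # (n, target, target) bool, optional

    def __post_init__(self) -> None:
        if len(self.index) != self.images.shape[0]:
            raise ValueError("index length must match image count")
        self.index = self.index.reset_index(drop=True)

    def __len__(self) -> int:
        return self.images.shape[0]

    def subset(self, rows) -> "ImageDataset":
        rows = np.asarray(rows)
        return ImageDataset(
            images=self.images[rows],
            index=self.index.iloc[rows].reset_index(drop=True),
            masks=None if self.masks is None else self.masks[rows])

    def save(self, path) -> None:
        np.savez_compressed(path, images=self.images,
                            masks=self.masks if self.masks is not None else np.zeros(0))
        pd.DataFrame(self.index).to_csv(str(path) + ".index.csv", index=False)

    @classmethod
    def load(cls, path) -> "ImageDataset":
        data = np.load(path)
        index = pd.read_csv(str(path) + ".index.csv")
        masks = data["masks"] if data["masks"].size else None
        return cls(images=data["images"], index=index, masks=masks)


def build_dataset(cohort: Cohort, target: int = 128, crop_frac: float = 0.5,
                  labeled_from_week: int | None = None,
                  keep_masks: bool = True) -> ImageDataset:
    """Prepare every slice of every cohort volume for the classifier.

    ``label`` is 1 for slices of induced subjects, 0 otherwise; downstream
    training restricts itself to the cleanly labeled weeks
    (``labeled_from_week`` merely annotates the index, it drops nothing).
    ``crop_frac`` is the fraction of axial rows kept (0.5 reproduces the
    top-512-of-1024 crop at any scale).
    """
    images, rows, masks = [], [], []
    for vol in cohort.volumes:
        depth = vol.voxels.shape[0]
        crop_rows = int(round(depth * crop_frac))
        flags = vol.slice_lesion_flags()
        for s in range(vol.n_slices):
            prep = prepare_image(vol.bscan(s),
                                 source=(vol.subject_id, vol.week, s),
                                 label=1 if vol.group == "induced" else 0,
                                 target=target, crop_rows=crop_rows)
            images.append(prep.pixels)
            if keep_masks and vol.lesion_mask is not None:
                masks.append(prepare_mask(vol.lesion_mask[:, :, s], target=target,
                                          crop_rows=crop_rows))
            rows.append({
                "subject_id": vol.subject_id, "group": vol.group,
                "week": vol.week, "slice": s,
                "label": 1 if vol.group == "induced" else 0,
                "lesion": bool(flags[s]),
                "labeled": (labeled_from_week is None
                            or vol.week >= labeled_from_week),
            })
    return ImageDataset(
        images=np.stack(images),
        index=pd.DataFrame(rows),
        masks=np.stack(masks) if masks else None)
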