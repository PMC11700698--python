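"""Class-activation-map interpretation of the trained classifier.

The network keeps VGG-style fully connected layers, so the classic CAM
formulation (which needs a global-average-pool head) does not apply directly;
a gradient-weighted activation map is used instead, which reduces to classic
CAM for GAP heads.  Per channel of the target convolutional block, the weight
is the spatial average of the positive gradients of the melanoma logit; the
map is the ReLU of the weighted activation sum, bilinearly upsampled to the
network input size and max-normalized to [0, 1] (all-zero maps stay zero).

The en-face view collapses depth by maximum: ``enface[s, x]`` is the largest
heatmap value in column ``x`` of slice ``s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

from .dl_model import Model


@dataclass
class CAMOutput:
    heatmap: np.ndarray  # (H, W) in [0, 1]
    raw_max: float  # pre-normalization maximum, for joint volume scaling


def compute_cam(model: Model, image: np.ndarray,
                layer_index: int | None = None) -> CAMOutput:
    """Gradient-weighted activation map for one prepared image."""
    if not model.trained:
        raise ValueError("model must be trained before computing CAMs")
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3:
        raise ValueError("image must be (H, W, 3)")
    act, grad = model.activation_and_gradient(image, layer_index)
    weights = np.mean(np.maximum(grad, 0.0), axis=(0, 1))  # (channels,)
    cam = np.maximum(np.tensordot(act, weights, axes=([2], [0])), 0.0)
    h, w = image.shape[:2]
    if cam.shape != (h, w):
        cam = resize(cam, (h, w), order=1, preserve_range=True,
                     anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    raw_max = float(cam.max())
    if raw_max > 0:
        cam = cam / raw_max
    return CAMOutput(heatmap=cam.astype(np.float32), raw_max=raw_max)


def enface_projection(heatmaps) -> np.ndarray:
    """Maximum over depth per slice and lateral position.

    ``heatmaps`` is a sequence (or array) of per-slice maps of identical
    shape; returns an (n_slices, lateral) map with rows ordered by slice.
    """
    heatmaps = [np.asarray(h) for h in heatmaps]
    if not heatmaps:
        raise ValueError("need >= 1 heatmap")
    shape = heatmaps[0].shape
    if any(h.shape != shape for h in heatmaps):
        raise ValueError("heatmaps must share one shape")
    return np.stack([h.max(axis=0) for h in heatmaps])


def overlay(gray: np.ndarray, heatmap: np.ndarray, alpha: float = 0.4,
            cmap: str = "jet", path=None) -> np.ndarray:
    """Alpha-blend a colormapped heatmap over a grayscale image (8-bit RGB)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    gray = np.asarray(gray, dtype=float)
    heatmap = np.asarray(heatmap, dtype=float)
    if gray.shape != heatmap.shape:
        raise ValueError("image and heatmap shapes must match")
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib import colormaps

    lo, hi = gray.min(), gray.max()
    g = (gray - lo) / (hi - lo) if hi > lo else np.zeros_like(gray)
    base = np.repeat(g[:, :, None], 3, axis=2)
    colored = colormaps[cmap](np.clip(heatmap, 0, 1))[:, :, :3]
    blended = (1.0 - alpha) * base + alpha * colored
    out = np.clip(np.round(blended * 255.0), 0, 255).astype(np.uint8)
    if path is not None:
        iio.imwrite(path, out)
    return out


def volume_cams(model: Model, images: np.ndarray,
                layer_index: int | None = None,
                joint_normalize: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Heatmaps for every slice of a volume plus the en-face projection.

    With ``joint_normalize`` the per-slice maps are rescaled by the volume-wide
    maximum so en-face intensities are comparable across slices.
    """
    maps, raw = [], []
    for s in range(images.shape[0]):
        out = compute_cam(model, images[s], layer_index)
        maps.append(out.heatmap)
        raw.append(out.raw_max)
    maps = np.stack(maps)
    if joint_normalize:
        raw = np.asarray(raw)
        vmax = raw.max()
        if vmax > 0:
            maps = maps * (raw[:, None, None] / vmax)
    return maps, enface_projection(maps)
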