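"""Grad-CAM, guided backpropagation and Guided Grad-CAM.

Grad-CAM weights each feature map of the deepest spatial layer by the
global average of the class-logit gradient over that map,

    alpha_k = (1/Z) * sum_ij  d y_c / d A_ij^k,

and the coarse localization map is the ReLU of the weighted sum,

    L = ReLU(sum_k alpha_k A^k).

Guided backpropagation computes the gradient of the class logit with
respect to the input pixels while zeroing the backward signal at every
activation site where either the incoming gradient or the forward
pre-activation is negative (the network uses Swish; the gate uses the
pre-activation sign).  Guided Grad-CAM is the pointwise product of the
bilinearly upsampled coarse map with the guided-backprop image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import cnn


@dataclass
class Heatmap:
    coarse: np.ndarray          # (u,v) >= 0
    gbp: np.ndarray             # (H,W,3) signed pixel gradients
    guided: np.ndarray          # (H,W) non-negative magnitude map
    guided_rgb: np.ndarray      # (H,W,3) signed per-channel product
    class_c: int
    tile_id: int = -1


def gradcam_weights(feature_maps: np.ndarray, gradients: np.ndarray
                    ) -> np.ndarray:
    """Global-average-pooled gradients, one weight per feature map.

    feature_maps, gradients: (u, v, K)."""
    if feature_maps.shape != gradients.shape:
        raise ValueError("feature map / gradient shape mismatch")
    return gradients.mean(axis=(0, 1))


def gradcam_map(feature_maps: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """ReLU-filtered weighted sum of the feature maps."""
    if feature_maps.shape[-1] != weights.shape[0]:
        raise ValueError("one weight per feature map required")
    return np.maximum(feature_maps @ weights, 0.0)


def gradcam(model: cnn.TileCNN, x: np.ndarray, class_c: int,
            layer: str = "conv3") -> np.ndarray:
    """Coarse map for one [0,1]-scaled tile (H,W,3) -> (u,v)."""
    batch = x[None]
    grads = cnn.class_gradient(model, layer, class_c, batch)[0]
    fmaps = model._taps[layer][0]
    return gradcam_map(fmaps, gradcam_weights(fmaps, grads))


def guided_backprop(model: cnn.TileCNN, x: np.ndarray, class_c: int
                    ) -> np.ndarray:
    """Signed pixel-gradient image with the guided gating rule applied
    at every activation."""
    return cnn.input_gradient(model, class_c, x[None], guided=True)[0]


def guided_gradcam(coarse: np.ndarray, gbp: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise product of the upsampled coarse map with the
    guided-backprop image.

    Returns (rgb, magnitude): the signed per-channel product used for
    display, and the non-negative map (upsampled coarse × |gbp|
    magnitude) used for quantitative checks."""
    h, w = gbp.shape[:2]
    up = resize(coarse, (h, w), order=1, mode="edge",
                anti_aliasing=False, preserve_range=True)
    rgb = up[..., None] * gbp
    magnitude = up * np.abs(gbp).sum(axis=-1)
    return rgb, magnitude


def compute_heatmap(model: cnn.TileCNN, tile_pixels: np.ndarray,
                    class_c: int, tile_id: int = -1) -> Heatmap:
    """Full pipeline for one uint8 tile."""
    x = tile_pixels.astype(np.float32) / 255.0
    coarse = gradcam(model, x, class_c)
    gbp = guided_backprop(model, x, class_c)
    rgb, mag = guided_gradcam(coarse, gbp)
    return Heatmap(coarse, gbp, mag, rgb, class_c, tile_id)


def _normalize_signed(img: np.ndarray) -> np.ndarray:
    """Signed image -> uint8 centered at 127 for display."""
    scale = np.abs(img).max()
    if scale == 0:
        return np.full(img.shape, 127, dtype=np.uint8)
    return np.clip(127.5 + 127.5 * img / scale, 0, 255).astype(np.uint8)


def render(tile_pixels: np.ndarray, heatmap: Heatmap, out_prefix: str
           ) -> list[str]:
    """Write the triptych: the tile, the coarse-map colour overlay, and
    the guided image.  Returns the three file paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from PIL import Image

    h, w = tile_pixels.shape[:2]
    paths = []

    p0 = f"{out_prefix}_tile.png"
    Image.fromarray(tile_pixels).save(p0)
    paths.append(p0)

    up = resize(heatmap.coarse, (h, w), order=1, mode="edge",
                anti_aliasing=False, preserve_range=True)
    denom = up.max() if up.max() > 0 else 1.0
    cmap = plt.get_cmap("jet")
    overlay = (0.5 * tile_pixels / 255.0
               + 0.5 * cmap(up / denom)[..., :3])
    p1 = f"{out_prefix}_gradcam.png"
    Image.fromarray(np.clip(overlay * 255, 0, 255).astype(np.uint8)).save(p1)
    paths.append(p1)

    p2 = f"{out_prefix}_guided.png"
    Image.fromarray(_normalize_signed(heatmap.guided_rgb)).save(p2)
    paths.append(p2)
    return paths
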