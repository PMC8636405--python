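"""Gradient-weighted class-activation maps for the pair-image classifier.

For a chosen convolutional layer and target class, the gradient of the
class logit with respect to the layer's (post-activation) feature maps
is combined with the activations into a spatial attribution grid, which
is rectified (negative contributions clipped), max-normalized and
bilinearly upsampled to the input geometry.  Three aggregation modes:

* ``"elementwise"`` (default): sum over channels of gradient x
  activation - the first-order contribution of each position to the
  class logit.  This network flattens the pooled feature maps into a
  dense layer, so every spatial position has its own read-out weights;
  position-resolved gradients are therefore the faithful attribution.
* ``"gradcam"``: classic formulation - gradients are first spatially
  averaged into one weight per channel, then channels are combined.
  With position-specific read-out weights the averaging mixes opposing
  signs and can cancel to empty maps; kept for comparability.
* ``"channel_mean"``: as ``"gradcam"`` but dividing by the channel
  count (a plain channel-wise mean); identical after normalization.

Because the pair image is a row of three panels (core, substituent of
the more potent compound, substituent of the less potent one), heat mass
can be attributed per panel by integrating the upsampled map over each
width third, which is how substituent-borne signals are quantified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .classifier import AC_CLASS, NON_AC_CLASS, CNNClassifier
from .errors import UsageError

logger = logging.getLogger(__name__)

#: Each convolutional layer's post-activation feature maps.
CONV_LAYERS = {"conv1": "relu1", "conv2": "relu2"}
CLASS_INDEX = {"AC": AC_CLASS, "NON_AC": NON_AC_CLASS}
MODES = ("elementwise", "gradcam", "channel_mean")
DEFAULT_MODE = "elementwise"


@dataclass(frozen=True)
class ActivationHeatmap:
    layer_id: str
    target_class: str
    grid: np.ndarray  # (h, w) non-negative, at the layer's resolution
    upsampled: np.ndarray  # (H, W) in [0, 1], input resolution


@dataclass(frozen=True)
class HeatmapOverlay:
    mmp_id: str
    image: np.ndarray  # (H, W, 3) uint8
    colormap: str


def _bilinear_resize(grid: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    h, w = grid.shape
    oh, ow = out_shape
    # sample output pixel centers in input pixel-center coordinates
    rows = (np.arange(oh) + 0.5) * h / oh - 0.5
    cols = (np.arange(ow) + 0.5) * w / ow - 0.5
    coords = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(grid, coords, order=1, mode="nearest")


def gradcam(
    model: CNNClassifier,
    image: np.ndarray,
    layer_id: str = "conv2",
    target_class: str = "AC",
    mode: str = DEFAULT_MODE,
) -> ActivationHeatmap:
    """Class-activation heatmap of one image from one conv layer.

    ``mode`` selects the aggregation (see module docstring); every mode
    is rectified and max-normalized.
    """
    if layer_id not in CONV_LAYERS:
        raise UsageError(f"unknown layer {layer_id!r}; choose from {sorted(CONV_LAYERS)}")
    if target_class not in CLASS_INDEX:
        raise UsageError(f"unknown class {target_class!r}")
    if mode not in MODES:
        raise UsageError(f"unknown aggregation mode {mode!r}; choose from {MODES}")
    image = np.ascontiguousarray(image, dtype=np.float32)
    if image.shape != model.config.input_shape:
        raise UsageError(
            f"gradcam: image shape {image.shape} != model input {model.config.input_shape}"
        )
    act_layer = CONV_LAYERS[layer_id]
    x = image[None]
    logits, outputs = model.net.forward(x, train=False, collect=True)
    activation = outputs[act_layer][0]  # (h, w, C)
    seed_grad = np.zeros_like(logits)
    seed_grad[0, CLASS_INDEX[target_class]] = 1.0
    grads = model.net.backward(seed_grad, to_layer=act_layer)[0]  # d logit / d activation
    if mode == "elementwise":
        cam = (activation * grads).sum(axis=2)
    else:
        channel_weights = grads.mean(axis=(0, 1))  # global-average-pooled gradients
        cam = activation @ channel_weights
        if mode == "channel_mean":
            cam = cam / activation.shape[-1]
    grid = np.maximum(cam, 0.0)
    peak = grid.max()
    norm = grid / peak if peak > 0 else grid
    upsampled = np.clip(_bilinear_resize(norm, image.shape[:2]), 0.0, 1.0)
    return ActivationHeatmap(
        layer_id=layer_id, target_class=target_class, grid=grid, upsampled=upsampled
    )


def panel_heat_fractions(upsampled: np.ndarray, n_panels: int = 3) -> np.ndarray:
    """Fraction of total heat mass in each width panel (sums to 1)."""
    width = upsampled.shape[1]
    edges = [round(i * width / n_panels) for i in range(n_panels + 1)]
    masses = np.array(
        [upsampled[:, edges[i] : edges[i + 1]].sum() for i in range(n_panels)], dtype=float
    )
    total = masses.sum()
    if total == 0:
        return np.full(n_panels, 1.0 / n_panels)
    return masses / total


def overlay(
    heatmap: ActivationHeatmap,
    base_image: np.ndarray,
    colormap: str = "jet",
    alpha: float = 0.5,
) -> HeatmapOverlay:
    """Alpha-blend the colorized heatmap over the grayscaled base image."""
    base_image = np.asarray(base_image, dtype=np.float32)
    if base_image.shape[:2] != heatmap.upsampled.shape:
        raise UsageError(
            f"overlay: base {base_image.shape[:2]} != heatmap {heatmap.upsampled.shape}"
        )
    gray = base_image.mean(axis=2, keepdims=True) * np.ones(3, dtype=np.float32)
    cmap = matplotlib.colormaps[colormap]
    heat_rgb = cmap(heatmap.upsampled)[..., :3].astype(np.float32)
    blended = (1.0 - alpha) * gray + alpha * heat_rgb
    image = np.clip(np.rint(blended * 255.0), 0, 255).astype(np.uint8)
    return HeatmapOverlay(mmp_id="", image=image, colormap=colormap)


def explain_batch(
    model: CNNClassifier,
    images: np.ndarray,
    mmp_ids,
    layer_ids=("conv1", "conv2"),
    target_class: str = "AC",
    mode: str = DEFAULT_MODE,
    out_dir=None,
    colormap: str = "jet",
) -> pd.DataFrame:
    """Heatmaps for a batch: optional overlay PNGs plus a per-panel summary.

    Returns a table with one row per (MMP, layer): the heat fraction in
    the core panel and in each substituent panel.
    """
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for img, mid in zip(images, mmp_ids):
        for layer_id in layer_ids:
            hm = gradcam(model, img, layer_id=layer_id, target_class=target_class, mode=mode)
            frac = panel_heat_fractions(hm.upsampled)
            rows.append(
                {
                    "mmp_id": mid,
                    "layer": layer_id,
                    "heat_core": frac[0],
                    "heat_sub_hi": frac[1],
                    "heat_sub_lo": frac[2],
                }
            )
            if out_dir is not None:
                ov = overlay(hm, img, colormap=colormap)
                Image.fromarray(ov.image).save(out_dir / f"{mid}_{layer_id}.png")
    return pd.DataFrame(rows, columns=["mmp_id", "layer", "heat_core", "heat_sub_hi", "heat_sub_lo"])
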