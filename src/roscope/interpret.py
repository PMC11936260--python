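"""Grad-CAM saliency for the trained classifiers plus an edge statistic.

Grad-CAM weights each feature map of a convolutional layer (the last one by
default) by the spatial average of the target-class logit gradient, takes the
ReLU of the weighted sum, bilinearly upsamples the result to the input grid
and normalizes it by its maximum.  Gradients are taken with respect to the
pre-softmax logit.

``edge_saliency_fraction`` turns the qualitative observation that saliency
concentrates at the cell edge into a number: the fraction of total saliency
mass inside a morphological band around the cell boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage import morphology, transform

from .model import CNNClassifier, image_to_input
from .preprocess import ProcessedSlice

logger = logging.getLogger("roscope.interpret")


@dataclass
class SaliencyMap:
    """Nonnegative saliency in input coordinates, max-normalized to [0, 1]."""

    values: np.ndarray
    target_class: int
    layer_name: str

    def validate(self) -> None:
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("saliency values must lie in [0, 1]")


def _last_conv_index(model: CNNClassifier) -> int:
    idx = [i for i, l in enumerate(model.spec.layers) if l.kind == "conv"]
    if not idx:
        raise ValueError("model has no convolutional layer")
    return idx[-1]


def grad_cam(model: CNNClassifier, image, target_class: int,
             layer: int | None = None) -> SaliencyMap:
    """Grad-CAM map for one slice and one target class.

    ``image`` is a ProcessedSlice or a 2D array (uint8 images are scaled to
    [0, 1] exactly as during training).  ``layer`` is an index into the
    architecture's layer list and must name a convolution; the default is the
    last convolutional layer.
    """
    if layer is None:
        layer = _last_conv_index(model)
    if model.spec.layers[layer].kind != "conv":
        raise ValueError(f"layer {layer} ({model.spec.layers[layer].name}) "
                         "is not convolutional")

    if isinstance(image, ProcessedSlice):
        image = image.pixels
    arr = np.asarray(image)
    if arr.dtype == np.uint8:
        arr = image_to_input(arr)  # same convention as training
    arr = arr.astype(np.float32)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[None]
    h_in, w_in = arr.shape[2], arr.shape[3]

    acts, grads = model.activation_and_gradient(arr, target_class, layer)
    weights = grads[0].mean(axis=(1, 2))  # spatial average per feature map
    cam = np.maximum((weights[:, None, None] * acts[0]).sum(axis=0), 0.0)
    cam = transform.resize(cam.astype(np.float64), (h_in, w_in), order=1,
                           preserve_range=True, anti_aliasing=False)
    cam = np.maximum(cam, 0.0)  # bilinear interpolation cannot overshoot, but be safe
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    out = SaliencyMap(values=cam, target_class=target_class,
                      layer_name=model.spec.layers[layer].name)
    out.validate()
    return out


def edge_saliency_fraction(smap: SaliencyMap | np.ndarray, footprint: np.ndarray,
                           band_px: int = 8) -> float:
    """Fraction of total saliency mass within ``band_px`` of the cell boundary.

    The boundary band is morphological: dilation minus erosion of the cell
    footprint by a disk of radius ``band_px``.  The footprint is resized to
    the saliency grid with nearest-neighbour interpolation if needed.
    Invariant to positive rescaling of the map; an identically zero map gives
    0 with a warning.
    """
    values = smap.values if isinstance(smap, SaliencyMap) else np.asarray(smap, dtype=float)
    fp = np.asarray(footprint).astype(bool)
    if not fp.any():
        raise ValueError("empty mask footprint")
    if fp.shape != values.shape:
        fp = transform.resize(fp.astype(float), values.shape, order=0,
                              preserve_range=True, anti_aliasing=False) > 0.5
        if not fp.any():
            raise ValueError("mask footprint vanished when resized to the saliency grid")
    disk = morphology.disk(band_px)
    band = morphology.dilation(fp, disk) & ~morphology.erosion(fp, disk)
    total = values.sum()
    if total <= 0:
        warnings.warn("zero saliency map: edge fraction defined as 0", stacklevel=2)
        return 0.0
    return float(values[band].sum() / total)


def saliency_overlay(image: np.ndarray, smap: SaliencyMap, path: str) -> None:
    """PNG of the input slice with the Grad-CAM heat map superimposed."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(image, cmap="gray")
    ax.imshow(smap.values, cmap="jet", alpha=0.4)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
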