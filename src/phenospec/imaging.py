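"""Pixel-wise chemical imaging: apply a selected-band PLS-DA model per pixel.

Every leaf pixel's spectrum at the selected wavelengths is pushed through
the trained regression vector, producing a 2-D map of predicted class
codes (0 = unstressed ... 100 = the farthest stressed group). Because the
model is linear, the mask-mean of the pixel map equals the prediction of
the leaf's mean spectrum exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .containers import HyperCube, LeafMask
from .pls import PLSModel, predict
from .selection import BandSelection

__all__ = ["PredictionMap", "predict_map", "render_map"]

#: predicted scores are clipped here before colormapping so extreme noise
#: pixels stay visible but bounded
SCORE_CLIP = (-20.0, 120.0)


@dataclass
class PredictionMap:
    """2-D predicted class-code scores over a leaf mask.

    ``values`` is NaN outside the mask; ``colormap_range`` sets the colour
    scale endpoints in code units (default full SPRI range 0-100).
    """

    values: np.ndarray
    mask: LeafMask
    colormap_range: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.pixels.shape:
            raise ValueError("map and mask shapes differ")
        lo, hi = self.colormap_range
        if not lo < hi:
            raise ValueError("colormap_range must satisfy lo < hi")

    def masked_mean(self) -> float:
        return float(np.nanmean(self.values[self.mask.pixels]))


def predict_map(
    cube: HyperCube,
    mask: LeafMask,
    model: PLSModel,
    selection: BandSelection | None = None,
    colormap_range: tuple[float, float] = (0.0, 100.0),
) -> PredictionMap:
    """Apply the model to each leaf pixel of ``cube``.

    When ``selection`` is given, its wavelengths are looked up on the cube
    grid by nearest band (the selection came from the same grid, so this
    is exact in practice) and the model must have been trained on exactly
    those bands. Without a selection the model must span the full cube.
    """
    if mask.pixels.shape != cube.data.shape[:2]:
        raise ValueError("mask spatial shape does not match the cube")
    if selection is not None:
        if selection.selected_wavelengths is None:
            raise ValueError("selection carries no wavelengths to locate in the cube")
        band_idx = []
        for w in selection.selected_wavelengths:
            i = cube.band_index(w)
            if abs(cube.wavelengths[i] - w) > max(5.0, np.diff(cube.wavelengths).max()):
                raise ValueError(f"cube has no band near {w:.1f} nm")
            band_idx.append(i)
        data = cube.data[:, :, band_idx]
    else:
        data = cube.data
    if data.shape[2] != model.n_bands:
        raise ValueError(
            f"model expects {model.n_bands} bands but {data.shape[2]} were extracted from the cube"
        )

    values = np.full(cube.data.shape[:2], np.nan)
    pix = data[mask.pixels].astype(float)
    values[mask.pixels] = predict(model, pix)
    return PredictionMap(values, mask, colormap_range)


def render_map(pmap: PredictionMap, out_path, colormap_name: str = "jet") -> None:
    """Write the map as an 8-bit colour PNG with a colourbar strip.

    No-data (background) pixels render neutral grey; values beyond the
    colormap range clamp to the endpoint colours. Output bytes are
    deterministic for identical inputs.
    """
    lo, hi = pmap.colormap_range
    cmap = colormaps[colormap_name]
    vals = np.clip(pmap.values, *SCORE_CLIP)
    norm = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)

    rgb = np.full(pmap.values.shape + (3,), 200, dtype=np.uint8)  # neutral background
    leaf = pmap.mask.pixels
    colored = (cmap(norm[leaf])[:, :3] * 255).astype(np.uint8)
    rgb[leaf] = colored

    # vertical colourbar: top = hi, bottom = lo
    h, w = rgb.shape[:2]
    bar_w = max(8, w // 12)
    grad = np.linspace(1.0, 0.0, h)
    bar = (cmap(grad)[:, :3] * 255).astype(np.uint8)
    bar = np.repeat(bar[:, None, :], bar_w, axis=1)
    gap = np.full((h, 2, 3), 255, dtype=np.uint8)
    panel = np.concatenate([rgb, gap, bar], axis=1)

    Image.fromarray(panel, mode="RGB").save(out_path, format="PNG")
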