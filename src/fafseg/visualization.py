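"""Feature-discovery views: attention heatmaps and deconvnet reconstructions.

Two complementary ways of seeing what the networks attend to:

* the *trainable* view -- per-level attention coefficient maps (alpha)
  from the self-attended model, upsampled to input resolution;
* the *post-hoc* view -- deconvnet reconstructions from the plain model,
  obtained by running the encoder blocks in reverse: activations, then
  transposed convolutions sharing the forward kernels, then unpooling
  that places each retained maximum back at its recorded switch
  location and zeroes everything else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .model import SegmentationModel
from .nn.layers import conv3x3_forward, relu, unpool2

__all__ = ["Heatmap", "attention_heatmap", "deconv_reconstruct", "save_heatmap_png"]


@dataclass
class Heatmap:
    """A display heatmap plus the raw (pre-rescale) values it came from."""

    values: np.ndarray      # min-max rescaled to [0, 1], input resolution
    raw: np.ndarray         # unrescaled map at input resolution
    source_level: int
    kind: str               # "attention" | "reconstruction"


def _rescale_display(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo < 1e-12:
        return np.zeros_like(arr, dtype=np.float64)
    return (arr - lo) / (hi - lo)


def attention_heatmap(model: SegmentationModel, image: np.ndarray, level: int) -> Heatmap:
    """Alpha map of one gated level, bilinearly upsampled to input resolution.

    Runs a forward pass, takes the level's attention coefficients, and
    returns both the raw alpha (preserved for quantitative use) and a
    min-max display rescale.
    """
    if not model.config.attended:
        raise ValueError("attention heatmaps require the attended model variant")
    model.net.forward(np.asarray(image, dtype=np.float32)[None, None])
    maps = model.net.attention_maps_
    if level not in maps:
        raise ValueError(
            f"level {level} has no attention gate; gated levels: {sorted(maps)}"
        )
    alpha = maps[level].alpha[0]
    raw = resize(alpha.astype(np.float64), image.shape, order=1, preserve_range=True)
    return Heatmap(values=_rescale_display(raw), raw=raw, source_level=level, kind="attention")


def deconv_reconstruct(model: SegmentationModel, image: np.ndarray, level: int) -> Heatmap:
    """Deconvnet reconstruction of the plain model from ``level`` back to the input.

    ``level`` indexes the encoder blocks (0..depth-1) or ``depth`` for
    the bottleneck.  Starting from that block's output, each block is
    inverted in reverse order: ReLU, transposed convolution of the
    block's second then first kernel (the forward weights, flipped --
    no reconstruction weights are trained), and switch-unpooling into
    the recorded max locations.  Channels are collapsed by the sum of
    absolute values for display.
    """
    if model.config.attended:
        raise ValueError("deconvnet reconstruction is defined for the plain variant")
    depth = model.config.depth
    if not 0 <= level <= depth:
        raise ValueError(f"level must be in 0..{depth} (encoder blocks + bottleneck)")
    net = model.net
    net.forward(np.asarray(image, dtype=np.float32)[None, None])
    if not net.pool_switches_:
        raise RuntimeError("no pooling switches recorded; run a forward pass first")

    r = net.encoder_feats_[level]
    for l in range(level, -1, -1):
        prefix = "bot" if l == depth else f"enc{l}"
        r = relu(r)
        r = _conv_transpose(r, net.params[f"{prefix}_c2_W"])
        r = relu(r)
        r = _conv_transpose(r, net.params[f"{prefix}_c1_W"])
        if l > 0:
            sw = net.pool_switches_[l - 1]
            n, c, h, w = r.shape
            r = unpool2(r, sw, (n, c, 2 * h, 2 * w))
    raw = np.abs(r[0]).sum(axis=0)
    return Heatmap(
        values=_rescale_display(raw), raw=raw, source_level=level, kind="reconstruction"
    )


def _conv_transpose(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """'Same' transposed convolution sharing the forward kernel (flipped)."""
    W_t = np.ascontiguousarray(W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    out, _ = conv3x3_forward(x, W_t, None)
    return out


def save_heatmap_png(heatmap: Heatmap, path, overlay: np.ndarray | None = None,
                     cmap: str = "inferno", blend: float = 0.55) -> None:
    """Write a color heatmap PNG, optionally blended over a grayscale image."""
    import matplotlib as mpl
    from PIL import Image

    rgba = mpl.colormaps[cmap](heatmap.values)
    rgb = rgba[..., :3]
    if overlay is not None:
        gray = np.clip(np.asarray(overlay, dtype=float), 0, 1)[..., None]
        rgb = blend * rgb + (1 - blend) * np.repeat(gray, 3, axis=2)
    Image.fromarray(np.round(rgb * 255).astype(np.uint8)).save(path)
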