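"""Model-level interface: building, soft prediction, thresholding, persistence.

Checkpoints are a ``.npz`` of the named parameter arrays plus a JSON
architecture descriptor recording the configuration and -- explicitly --
which sigmoid form the gates use.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .nn.network import SIGMA2_FORM, NetworkConfig, UNet

__all__ = ["NetworkConfig", "SegmentationModel", "build_model", "predict_soft", "binarize"]


class SegmentationModel:
    """A configured network plus convenience accessors.

    ``attention_maps`` and ``pooling_switches`` expose the taps recorded
    by the most recent forward pass (per decoder level / per encoder
    pool respectively).
    """

    def __init__(self, config: NetworkConfig, net: UNet | None = None):
        self.config = config
        self.net = net if net is not None else UNet(config)

    @property
    def attention_maps(self):
        return self.net.attention_maps_

    @property
    def pooling_switches(self):
        return self.net.pool_switches_

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net.params)
        descriptor = dataclasses.asdict(self.config)
        descriptor["sigma2"] = SIGMA2_FORM
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(descriptor, fh, indent=2)

    @classmethod
    def load(cls, path) -> "SegmentationModel":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            d = json.load(fh)
        d.pop("sigma2", None)
        model = cls(NetworkConfig(**d))
        with np.load(path.with_suffix(".npz")) as npz:
            model.net.set_params_({k: npz[k] for k in npz.files})
        return model


def build_model(config: NetworkConfig) -> SegmentationModel:
    """Instantiate a plain or attention-gated model from its configuration."""
    return SegmentationModel(config)


def predict_soft(model: SegmentationModel, image: np.ndarray) -> np.ndarray:
    """Soft-label probability map for one standardized grayscale image."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError(f"predict_soft expects a single 2-D image, got {image.shape}")
    prob = model.net.forward(image[None, None])
    return prob[0, 0]


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map: mask = (prob >= threshold)."""
    prob = np.asarray(prob)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map must lie in [0, 1]")
    return (prob >= threshold).astype(np.uint8)
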