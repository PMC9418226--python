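"""Plain and attention-gated encoder-decoder segmentation networks.

The architecture is a U-shaped fully convolutional network: a
contracting path of levels with two 3x3 conv + ReLU layers each and 2x2
max pooling, a two-conv bottleneck, and a symmetric expanding path in
which coarser features are upsampled, convolved, and concatenated with
the same-resolution encoder features through skip connections.  The
final 1x1 convolution and logistic activation produce a one-channel
soft-label probability map.

The attended variant is topologically identical except that every skip
connection first passes through a trainable attention gate: the encoder
features are rescaled per pixel by a coefficient alpha in [0, 1]
computed from the features themselves and the upsampled coarser decoder
features (the gating signal).  Per-level alpha maps and max-pool
switches are retained after every forward pass for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gate import AttentionGateParams, AttentionMap, attention_gate, attention_gate_backward
from .layers import (
    BufferPool as layers_pool,
    conv1x1_backward,
    conv1x1_forward,
    conv3x3_backward,
    conv3x3_forward,
    maxpool2,
    maxpool2_backward,
    relu,
    sigmoid,
    upsample2,
    upsample2_backward,
)

__all__ = ["NetworkConfig", "UNet"]

#: Text recorded in every architecture descriptor: which sigma_2 the gate uses.
SIGMA2_FORM = "logistic: alpha = 1 / (1 + exp(-a / T))"


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``f_int_ratio`` sets each gate's intermediate dimension as
    ``F_int = max(1, floor(F_l * f_int_ratio))``.  ``temperature`` is
    the soft-label temperature of the gate sigmoid (1 by default).
    """

    depth: int = 3
    base_filters: int = 8
    f_int_ratio: float = 0.5
    temperature: float = 1.0
    input_size: int = 128
    attended: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^depth = {2**self.depth}"
            )

    def encoder_channels(self) -> list[int]:
        return [self.base_filters * 2**i for i in range(self.depth)]

    def bottleneck_channels(self) -> int:
        return self.base_filters * 2**self.depth

    def f_int(self, level: int) -> int:
        return max(1, int(self.encoder_channels()[level] * self.f_int_ratio))


class UNet:
    """The network with explicit parameters and hand-written backprop.

    Parameters live in ``self.params`` (name -> float32 array) and are
    updated in place by the optimizer.  ``forward`` keeps per-level
    attention maps in ``attention_maps_``, max-pool switches in
    ``pool_switches_`` and pre-pool encoder block outputs (plus the
    bottleneck) in ``encoder_feats_``; with ``train=True`` it caches the
    intermediates needed by ``backward``.
    """

    def __init__(self, config: NetworkConfig):
        config.validate()
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self._pool = layers_pool()
        self._rng = np.random.default_rng(config.seed)
        self._build()
        self._cache: dict = {}
        self.attention_maps_: dict[int, AttentionMap] = {}
        self.pool_switches_: list[np.ndarray] = []
        self.encoder_feats_: list[np.ndarray] = []

    # ------------------------------------------------------------ build

    def _init_conv(self, name: str, c_out: int, c_in: int, k: int) -> None:
        fan_in = c_in * k * k
        limit = np.sqrt(6.0 / fan_in)
        shape = (c_out, c_in, k, k) if k == 3 else (c_out, c_in)
        self.params[name + "_W"] = self._rng.uniform(-limit, limit, shape).astype(np.float32)
        self.params[name + "_b"] = np.zeros(c_out, dtype=np.float32)

    def _build(self) -> None:
        cfg = self.config
        enc = cfg.encoder_channels()
        c_bot = cfg.bottleneck_channels()
        c_in = 1
        for i, c in enumerate(enc):
            self._init_conv(f"enc{i}_c1", c, c_in, 3)
            self._init_conv(f"enc{i}_c2", c, c, 3)
            c_in = c
        self._init_conv("bot_c1", c_bot, enc[-1], 3)
        self._init_conv("bot_c2", c_bot, c_bot, 3)
        for i in reversed(range(cfg.depth)):
            c_above = c_bot if i == cfg.depth - 1 else enc[i + 1]
            self._init_conv(f"dec{i}_up", enc[i], c_above, 3)
            if cfg.attended:
                f_int = cfg.f_int(i)
                lim_x = np.sqrt(6.0 / enc[i])
                lim_p = np.sqrt(6.0 / f_int)
                self.params[f"gate{i}_w_x"] = self._rng.uniform(
                    -lim_x, lim_x, (enc[i], f_int)).astype(np.float32)
                self.params[f"gate{i}_w_s"] = self._rng.uniform(
                    -lim_x, lim_x, (enc[i], f_int)).astype(np.float32)
                self.params[f"gate{i}_psi"] = self._rng.uniform(
                    -lim_p, lim_p, f_int).astype(np.float32)
                self.params[f"gate{i}_b_g"] = np.zeros(f_int, dtype=np.float32)
                self.params[f"gate{i}_b_psi"] = np.zeros(1, dtype=np.float32)
            self._init_conv(f"dec{i}_c1", enc[i], 2 * enc[i], 3)
            self._init_conv(f"dec{i}_c2", enc[i], enc[i], 3)
        self._init_conv("out", 1, enc[0], 1)

    def gate_params(self, level: int) -> AttentionGateParams:
        if not self.config.attended:
            raise ValueError("plain model has no attention gates")
        p = self.params
        return AttentionGateParams(
            w_x=p[f"gate{level}_w_x"], w_s=p[f"gate{level}_w_s"],
            psi=p[f"gate{level}_psi"], b_g=p[f"gate{level}_b_g"],
            b_psi=p[f"gate{level}_b_psi"],
        )

    @property
    def n_parameters(self) -> int:
        return sum(int(v.size) for v in self.params.values())

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params_(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k][...] = params[k]

    def copy_shared_weights_from(self, other: "UNet") -> None:
        """Copy every parameter both variants share (everything but gates)."""
        for k, v in other.params.items():
            if k in self.params:
                self.params[k][...] = v

    # ---------------------------------------------------------- forward

    def _conv_relu(self, name: str, x: np.ndarray, train: bool) -> np.ndarray:
        W, b = self.params[name + "_W"], self.params[name + "_b"]
        pre, cols = conv3x3_forward(x, W, b, pool=self._pool, key=name)
        if train:
            self._cache[name] = (cols, pre, x.shape)
        return relu(pre)

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        force_alpha: float | None = None,
    ) -> np.ndarray:
        """Run the network; returns the (N, 1, H, W) probability map.

        ``force_alpha`` clamps every gate coefficient to a constant
        (e.g. 1.0 to make the attended variant behave exactly like the
        plain one); it is an inference-only diagnostic.
        """
        cfg = self.config
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[2] != cfg.input_size or x.shape[3] != cfg.input_size:
            raise ValueError(
                f"input is {x.shape[2]}x{x.shape[3]} but the model expects "
                f"{cfg.input_size}x{cfg.input_size}"
            )
        if train and force_alpha is not None:
            raise ValueError("force_alpha is inference-only")
        self._cache = {}
        self.attention_maps_ = {}
        self.pool_switches_ = []
        self.encoder_feats_ = []

        h = x
        skips = []
        for i in range(cfg.depth):
            h = self._conv_relu(f"enc{i}_c1", h, train)
            h = self._conv_relu(f"enc{i}_c2", h, train)
            skips.append(h)
            self.encoder_feats_.append(h)
            if train:
                self._cache[f"pool{i}_shape"] = h.shape
            h, sw = maxpool2(h)
            self.pool_switches_.append(sw)
        h = self._conv_relu("bot_c1", h, train)
        h = self._conv_relu("bot_c2", h, train)
        self.encoder_feats_.append(h)

        for i in reversed(range(cfg.depth)):
            up = upsample2(h)
            s = self._conv_relu(f"dec{i}_up", up, train)
            xs = skips[i]
            if cfg.attended:
                if force_alpha is None:
                    gated, att, gc = attention_gate(
                        xs, s, self.gate_params(i), cfg.temperature, return_cache=True
                    )
                    self.attention_maps_[i] = att
                    if train:
                        self._cache[f"gate{i}"] = gc
                else:
                    gated = xs * force_alpha
                    n, _, hh, ww = xs.shape
                    self.attention_maps_[i] = AttentionMap(
                        pre_activation=np.full((n, hh, ww), np.nan, np.float32),
                        alpha=np.full((n, hh, ww), force_alpha, np.float32),
                    )
            else:
                gated = xs
            h = np.concatenate([gated, s], axis=1)
            h = self._conv_relu(f"dec{i}_c1", h, train)
            h = self._conv_relu(f"dec{i}_c2", h, train)

        logits = conv1x1_forward(h, self.params["out_W"], self.params["out_b"])
        if train:
            self._cache["out_x"] = h
        self.logits_ = logits
        return sigmoid(logits)

    # --------------------------------------------------------- backward

    def _conv_relu_bwd(self, name: str, dout: np.ndarray, grads: dict,
                       need_dx: bool = True) -> np.ndarray:
        cols, pre, x_shape = self._cache[name]
        if dout.base is None and dout.flags.writeable:
            dy = np.multiply(dout, pre > 0, out=dout)   # dout is never reused
        else:
            dy = dout * (pre > 0)
        dx, dW, db = conv3x3_backward(dy, cols, self.params[name + "_W"], x_shape,
                                      pool=self._pool, key=name, need_dx=need_dx)
        grads[name + "_W"] = dW
        grads[name + "_b"] = db
        return dx

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Backprop from d(loss)/d(logits); returns gradients for every parameter."""
        if not self._cache:
            raise RuntimeError("backward requires a preceding forward(train=True)")
        cfg = self.config
        grads: dict[str, np.ndarray] = {}
        dh, dW, db = conv1x1_backward(
            dlogits, self._cache["out_x"], self.params["out_W"]
        )
        grads["out_W"], grads["out_b"] = dW, db

        dskips: dict[int, np.ndarray] = {}
        for i in range(cfg.depth):          # reverse of the decoder loop
            dh = self._conv_relu_bwd(f"dec{i}_c2", dh, grads)
            dh = self._conv_relu_bwd(f"dec{i}_c1", dh, grads)
            c_i = cfg.encoder_channels()[i]
            dgated, ds = dh[:, :c_i], dh[:, c_i:]
            if cfg.attended:
                dxs, ds_gate, ggrads = attention_gate_backward(
                    dgated, self._cache[f"gate{i}"]
                )
                for field, g in ggrads.items():
                    grads[f"gate{i}_{field}"] = g.astype(np.float32)
                ds = ds + ds_gate
            else:
                dxs = dgated
            dskips[i] = dxs
            d_up = self._conv_relu_bwd(f"dec{i}_up", ds, grads)
            dh = upsample2_backward(d_up)

        dh = self._conv_relu_bwd("bot_c2", dh, grads)
        dh = self._conv_relu_bwd("bot_c1", dh, grads)
        for i in reversed(range(cfg.depth)):
            dh = maxpool2_backward(dh, self.pool_switches_[i], self._cache[f"pool{i}_shape"])
            dh = dh + dskips[i]
            dh = self._conv_relu_bwd(f"enc{i}_c2", dh, grads)
            dh = self._conv_relu_bwd(f"enc{i}_c1", dh, grads, need_dx=(i > 0))
        return grads
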