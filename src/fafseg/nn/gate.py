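"""The trainable attention gate that modulates skip connections.

For every pixel ``i`` of a skip feature map ``x`` (``F_l`` channels) and
its spatially aligned gating signal ``s`` (``F_s`` channels, the
upsampled coarser decoder features), the gate computes

    a_i     = psi . relu(W_x' x_i + W_s' s_i + b_g) + b_psi
    alpha_i = logistic(a_i / T)
    gated_i = alpha_i * x_i

with the scalar coefficient broadcast across the channels of ``x``.
``T`` is the soft-label temperature: T -> infinity drives every alpha to
0.5 (softest labels) while small T sharpens alpha toward {0, 1}.  The
logistic here is the bounded sigmoid 1/(1+exp(-a/T)), which is the form
consistent with alpha being a probability in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import relu, sigmoid

__all__ = ["AttentionGateParams", "AttentionMap", "attention_gate", "attention_gate_backward"]


@dataclass
class AttentionGateParams:
    """Trainable gate parameters; shapes follow the linear maps above."""

    w_x: np.ndarray    # (F_l, F_int)
    w_s: np.ndarray    # (F_s, F_int)
    psi: np.ndarray    # (F_int,)
    b_g: np.ndarray    # (F_int,)
    b_psi: np.ndarray  # shape (1,)

    def validate(self) -> None:
        f_int = self.w_x.shape[1]
        if self.w_s.shape[1] != f_int:
            raise ValueError(
                f"W_s intermediate dim {self.w_s.shape[1]} != W_x's {f_int}"
            )
        if self.psi.shape != (f_int,):
            raise ValueError(f"psi must have shape ({f_int},), got {self.psi.shape}")
        if self.b_g.shape != (f_int,):
            raise ValueError(f"b_g must have shape ({f_int},), got {self.b_g.shape}")

    @property
    def n_parameters(self) -> int:
        return self.w_x.size + self.w_s.size + self.psi.size + self.b_g.size + 1


@dataclass
class AttentionMap:
    """Per-pixel gate output: pre-activation ``a`` and coefficient ``alpha``."""

    pre_activation: np.ndarray   # (N, H, W)
    alpha: np.ndarray            # (N, H, W), in [0, 1]


def _batched(arr: np.ndarray):
    if arr.ndim == 3:
        return arr[None], True
    if arr.ndim == 4:
        return arr, False
    raise ValueError(f"expected (C, H, W) or (N, C, H, W), got shape {arr.shape}")


def attention_gate(
    x: np.ndarray,
    s: np.ndarray,
    params: AttentionGateParams,
    T: float = 1.0,
    return_cache: bool = False,
):
    """Apply the attention gate; returns ``(gated, AttentionMap)``.

    ``x`` and ``s`` must already be spatially aligned (the gating signal
    is resampled before the gate).  With ``return_cache=True`` a third
    element carrying intermediates for :func:`attention_gate_backward`
    is appended.
    """
    if T <= 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    params.validate()
    x, squeeze = _batched(np.asarray(x))
    s, _ = _batched(np.asarray(s))
    if x.shape[0] != s.shape[0] or x.shape[2:] != s.shape[2:]:
        raise ValueError(
            f"x and s must be spatially aligned: x {x.shape} vs s {s.shape}"
        )
    if x.shape[1] != params.w_x.shape[0]:
        raise ValueError(
            f"x has {x.shape[1]} channels but W_x expects {params.w_x.shape[0]} (F_l)"
        )
    if s.shape[1] != params.w_s.shape[0]:
        raise ValueError(
            f"s has {s.shape[1]} channels but W_s expects {params.w_s.shape[0]} (F_s)"
        )
    N, Fl, H, W = x.shape
    xm = x.reshape(N, Fl, H * W)
    sm = s.reshape(N, s.shape[1], H * W)
    pre = (
        np.matmul(params.w_x.T, xm)
        + np.matmul(params.w_s.T, sm)
        + params.b_g.reshape(1, -1, 1)
    )                                            # (N, F_int, HW)
    hid = relu(pre)
    a = np.einsum("f,nfp->np", params.psi, hid) + np.asarray(params.b_psi).reshape(-1)[0]
    alpha = sigmoid(a / T)                       # (N, HW)
    gated = x * alpha.reshape(N, 1, H, W)
    att = AttentionMap(
        pre_activation=a.reshape(N, H, W)[0] if squeeze else a.reshape(N, H, W),
        alpha=alpha.reshape(N, H, W)[0] if squeeze else alpha.reshape(N, H, W),
    )
    out = gated[0] if squeeze else gated
    if not return_cache:
        return out, att
    cache = dict(x=x, xm=xm, sm=sm, pre=pre, hid=hid,
                 alpha=alpha.reshape(N, 1, H, W), T=T, params=params)
    return out, att, cache


def attention_gate_backward(dgated: np.ndarray, cache: dict):
    """Backward pass; returns ``(dx, ds, grads)`` with grads keyed by field name."""
    p: AttentionGateParams = cache["params"]
    x, xm, sm = cache["x"], cache["xm"], cache["sm"]
    pre, hid, alpha, T = cache["pre"], cache["hid"], cache["alpha"], cache["T"]
    N, Fl, H, W = x.shape
    HW = H * W

    dalpha = (dgated * x).sum(axis=1, keepdims=True)          # (N,1,H,W)
    dx = dgated * alpha
    da = (dalpha * alpha * (1.0 - alpha) / T).reshape(N, HW)  # (N, HW)
    dpsi = np.einsum("np,nfp->f", da, hid)
    dhid = p.psi.reshape(1, -1, 1) * da[:, None, :]
    dpre = dhid * (pre > 0)
    dw_x = np.tensordot(xm, dpre, axes=([0, 2], [0, 2]))      # (F_l, F_int)
    dw_s = np.tensordot(sm, dpre, axes=([0, 2], [0, 2]))
    db_g = dpre.sum(axis=(0, 2))
    db_psi = np.array([da.sum()], dtype=dpsi.dtype)
    dx = dx + np.matmul(p.w_x, dpre).reshape(N, Fl, H, W)
    ds = np.matmul(p.w_s, dpre).reshape(N, sm.shape[1], H, W)
    grads = {"w_x": dw_x, "w_s": dw_s, "psi": dpsi, "b_g": db_g, "b_psi": db_psi}
    return dx, ds, grads
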