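"""Coordinate Attention forward pass as pure array operations.

Coordinate Attention factorises channel attention into two 1-D poolings —
one along image width and one along height — so the resulting attention
maps carry positional information in each direction.  The block here is
inference-only: its 1x1 transforms are injected as plain matrices, there is
no training and no batch normalisation (identity in inference style).

Shapes follow the (channel, row, column) convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["CAWeights", "coordinate_attention"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class CAWeights:
    """1x1-convolution weights of a Coordinate Attention block.

    ``reduce``  maps C -> C//r channels (matrix of shape (C//r, C)),
    ``expand_h`` and ``expand_w`` map C//r -> C (shape (C, C//r)); each has
    a bias vector.  ``r`` is the channel reduction ratio and must divide C.
    """

    reduce: np.ndarray
    reduce_bias: np.ndarray
    expand_h: np.ndarray
    expand_h_bias: np.ndarray
    expand_w: np.ndarray
    expand_w_bias: np.ndarray
    r: int = 32

    @property
    def channels(self) -> int:
        return self.reduce.shape[1]

    def validate(self) -> None:
        c = self.channels
        if c % self.r != 0:
            raise ValueError(f"reduction ratio {self.r} must divide channel count {c}")
        cr = c // self.r
        checks = {
            "reduce": (self.reduce.shape, (cr, c)),
            "reduce_bias": (self.reduce_bias.shape, (cr,)),
            "expand_h": (self.expand_h.shape, (c, cr)),
            "expand_h_bias": (self.expand_h_bias.shape, (c,)),
            "expand_w": (self.expand_w.shape, (c, cr)),
            "expand_w_bias": (self.expand_w_bias.shape, (c,)),
        }
        for name, (got, want) in checks.items():
            if tuple(got) != want:
                raise ValueError(f"{name} has shape {got}, expected {want}")

    @classmethod
    def zeros(cls, channels: int, r: int = 32) -> "CAWeights":
        cr = channels // r
        if cr * r != channels:
            raise ValueError(f"reduction ratio {r} must divide channel count {channels}")
        return cls(
            reduce=np.zeros((cr, channels)),
            reduce_bias=np.zeros(cr),
            expand_h=np.zeros((channels, cr)),
            expand_h_bias=np.zeros(channels),
            expand_w=np.zeros((channels, cr)),
            expand_w_bias=np.zeros(channels),
            r=r,
        )

    @classmethod
    def random(cls, channels: int, r: int = 32, seed: int = 0, scale: float = 0.1) -> "CAWeights":
        rng = np.random.default_rng(seed)
        w = cls.zeros(channels, r)
        cr = channels // r
        return cls(
            reduce=rng.normal(0, scale, (cr, channels)),
            reduce_bias=rng.normal(0, scale, cr),
            expand_h=rng.normal(0, scale, (channels, cr)),
            expand_h_bias=rng.normal(0, scale, channels),
            expand_w=rng.normal(0, scale, (channels, cr)),
            expand_w_bias=rng.normal(0, scale, channels),
            r=r,
        )

    def save_npz(self, path: str | Path) -> None:
        np.savez(
            path,
            reduce=self.reduce,
            reduce_bias=self.reduce_bias,
            expand_h=self.expand_h,
            expand_h_bias=self.expand_h_bias,
            expand_w=self.expand_w,
            expand_w_bias=self.expand_w_bias,
            r=np.array(self.r),
        )

    @classmethod
    def load_npz(cls, path: str | Path) -> "CAWeights":
        with np.load(path) as data:
            return cls(
                reduce=data["reduce"],
                reduce_bias=data["reduce_bias"],
                expand_h=data["expand_h"],
                expand_h_bias=data["expand_h_bias"],
                expand_w=data["expand_w"],
                expand_w_bias=data["expand_w_bias"],
                r=int(data["r"]),
            )

    def save_json(self, path: str | Path) -> None:
        obj = {
            k: getattr(self, k).tolist()
            for k in (
                "reduce",
                "reduce_bias",
                "expand_h",
                "expand_h_bias",
                "expand_w",
                "expand_w_bias",
            )
        }
        obj["r"] = self.r
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def load_json(cls, path: str | Path) -> "CAWeights":
        obj = json.loads(Path(path).read_text())
        arrays = {k: np.asarray(v, dtype=float) for k, v in obj.items() if k != "r"}
        return cls(r=int(obj["r"]), **arrays)


def coordinate_attention(
    x: np.ndarray, w: CAWeights, return_maps: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply a Coordinate Attention block to a (C, H, W) feature map.

    Steps: pool along width and along height, concatenate the two pooled
    profiles, apply the shared ``reduce`` transform with a ReLU, split back,
    apply ``expand_h`` / ``expand_w``, squash each through a logistic to get
    attention maps ``a_h`` (C x H) and ``a_w`` (C x W), and gate the input:
    ``out[c, i, j] = x[c, i, j] * a_h[c, i] * a_w[c, j]``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"expected (C, H, W) input, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map must be finite")
    w.validate()
    c, h_dim, w_dim = x.shape
    if c != w.channels:
        raise ValueError(f"input has {c} channels but weights expect {w.channels}")

    pooled_h = x.mean(axis=2)  # (C, H): mean over columns
    pooled_w = x.mean(axis=1)  # (C, W): mean over rows
    z = np.concatenate([pooled_h, pooled_w], axis=1)  # (C, H+W)

    mid = np.maximum(w.reduce @ z + w.reduce_bias[:, None], 0.0)  # (C//r, H+W)
    mid_h, mid_w = mid[:, :h_dim], mid[:, h_dim:]

    a_h = _sigmoid(w.expand_h @ mid_h + w.expand_h_bias[:, None])  # (C, H)
    a_w = _sigmoid(w.expand_w @ mid_w + w.expand_w_bias[:, None])  # (C, W)

    out = x * a_h[:, :, None] * a_w[:, None, :]
    if return_maps:
        return out, a_h, a_w
    return out
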