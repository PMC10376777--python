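"""Windowed multi-head self-attention and the parallel attention block.

Tokens live on an (H, W) grid with C channels; batched tensors are
(B, H, W, C).  Attention is restricted to non-overlapping S×S windows
(WMSA).  The shifted variant (SWMSA) cyclically shifts the grid by half a
window before partitioning, so that information crosses window borders, and
masks out the token pairs that the cyclic shift wrapped around from opposite
sides of the image.

The parallel attention block runs a WMSA path and an SWMSA path on the *same*
input independently and sums the two outputs:

    F'    = MLP(LN(WMSA(LN(F)) + F)) + (WMSA(LN(F)) + F)
    F''   = MLP(LN(SWMSA(LN(F)) + F)) + (SWMSA(LN(F)) + F)
    F_out = F' + F''
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (DEFAULT_DTYPE, Linear, Module, Parameter, Tensor, gelu,
                       crop2d, pad2d, roll2d, softmax, take, trunc_normal)

MASK_VALUE = -1e9


@dataclass
class AttentionConfig:
    """Geometry of one window-attention layer."""
    window_size: int
    num_heads: int
    head_dim: int
    shift: int = 0

    @property
    def channels(self) -> int:
        return self.num_heads * self.head_dim

    def __post_init__(self):
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if not 0 <= self.shift < self.window_size:
            raise ValueError("shift must satisfy 0 <= shift < window_size")


def check_finite(x: Tensor, stage: str) -> Tensor:
    if not np.all(np.isfinite(x.data)):
        raise ValueError(f"non-finite values entering {stage}")
    return x


class LayerNorm(Module):
    """Per-token normalization over the channel axis: (x-μ)/√(σ²+ε)·γ + β."""

    def __init__(self, dim: int, eps: float = 1e-5, name: str = "layer_norm"):
        if eps <= 0:
            raise ValueError("epsilon must be positive")
        self.gain = Parameter(np.ones(dim, dtype=DEFAULT_DTYPE))
        self.bias = Parameter(np.zeros(dim, dtype=DEFAULT_DTYPE))
        self._eps = eps
        self._name = name

    def __call__(self, x: Tensor) -> Tensor:
        check_finite(x, self._name)
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        y = xc * ((var + self._eps) ** -0.5)
        return y * self.gain + self.bias


def layer_norm(x: Tensor, gain, bias, eps: float = 1e-5, stage: str = "layer_norm") -> Tensor:
    """Functional layer normalization over the last (channel) axis."""
    if eps <= 0:
        raise ValueError("epsilon must be positive")
    check_finite(x, stage)
    gain = gain if isinstance(gain, Tensor) else Tensor(gain)
    bias = bias if isinstance(bias, Tensor) else Tensor(bias)
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * ((var + eps) ** -0.5) * gain + bias


class Mlp(Module):
    """Two linear maps around a GELU: Linear(GELU(Linear(x)))."""

    def __init__(self, rng: np.random.Generator, dim: int, expansion_ratio: int = 4):
        hidden = expansion_ratio * dim
        self.fc1 = Linear(rng, dim, hidden)
        self.fc2 = Linear(rng, hidden, dim)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


# ---------------------------------------------------------------------------
# window bookkeeping
# ---------------------------------------------------------------------------

def window_partition(x: Tensor, window_size: int) -> Tensor:
    """(B, H, W, C) -> (B·nW, S·S, C) with H, W divisible by S."""
    if window_size <= 0:
        raise ValueError("window size must be positive")
    B, H, W, C = x.shape
    S = window_size
    if H % S or W % S:
        raise ValueError(f"grid {H}x{W} not divisible by window size {S}")
    x = x.reshape(B, H // S, S, W // S, S, C)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(B * (H // S) * (W // S), S * S, C)


def window_reverse(windows: Tensor, window_size: int, height: int, width: int) -> Tensor:
    """Inverse of :func:`window_partition`."""
    S = window_size
    nH, nW = height // S, width // S
    B = windows.shape[0] // (nH * nW)
    x = windows.reshape(B, nH, nW, S, S, windows.shape[-1])
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(B, height, width, windows.shape[-1])


def relative_position_index(window_size: int) -> np.ndarray:
    """(S², S²) table of flattened (Δrow, Δcol) offsets within a window."""
    S = window_size
    coords = np.stack(np.meshgrid(np.arange(S), np.arange(S), indexing="ij"))
    coords = coords.reshape(2, -1)
    rel = coords[:, :, None] - coords[:, None, :]          # (2, N, N)
    rel = rel + (S - 1)                                     # shift to >= 0
    return (rel[0] * (2 * S - 1) + rel[1]).astype(np.int64)


def swmsa_mask(height: int, width: int, window_size: int, shift: int,
               valid: np.ndarray | None = None) -> np.ndarray | None:
    """Additive attention mask for the shifted-window scheme.

    After rolling the grid by (-shift, -shift), tokens that were wrapped
    around from the opposite border land in the same window as tokens they
    should not attend to.  Every token is labelled with the region it came
    from; pairs with different labels get ``MASK_VALUE``.  ``valid`` marks
    real (non padding) tokens; padding tokens are masked out as keys.

    Returns an (nWindows, S², S²) array, or None when no masking is needed.
    """
    S = window_size
    need_shift = shift > 0
    need_pad = valid is not None and not valid.all()
    if not need_shift and not need_pad:
        return None

    # region labels live in the *rolled* frame: after rolling by (-shift,
    # -shift) the bottom/right `shift` rows/cols hold the wrapped content,
    # the S-shift rows/cols above them hold the opposite border
    ids = np.zeros((height, width), dtype=np.int64)
    if need_shift:
        marks_h = (slice(0, height - S), slice(height - S, height - shift),
                   slice(height - shift, height))
        marks_w = (slice(0, width - S), slice(width - S, width - shift),
                   slice(width - shift, width))
        cnt = 0
        for mh in marks_h:
            for mw in marks_w:
                ids[mh, mw] = cnt
                cnt += 1

    if valid is None:
        valid = np.ones((height, width), dtype=bool)
    elif need_shift:
        valid = np.roll(valid, (-shift, -shift), axis=(0, 1))

    nH, nW = height // S, width // S
    ids_w = ids.reshape(nH, S, nW, S).transpose(0, 2, 1, 3).reshape(-1, S * S)
    val_w = valid.reshape(nH, S, nW, S).transpose(0, 2, 1, 3).reshape(-1, S * S)

    mask = np.where(ids_w[:, :, None] != ids_w[:, None, :], MASK_VALUE, 0.0)
    mask = np.where(val_w[:, None, :], mask, MASK_VALUE)    # padding never a key
    # a padding *query* row may end up with no permitted key; let it attend
    # uniformly (its output is cropped away after window_reverse)
    dead = (mask <= MASK_VALUE / 2).all(axis=-1)
    mask[dead] = 0.0
    return mask.astype(DEFAULT_DTYPE)


# ---------------------------------------------------------------------------
# attention layers
# ---------------------------------------------------------------------------

class WindowAttention(Module):
    """Multi-head self-attention within one set of windows.

    softmax(QKᵀ/√d + b)V per head, where b is a learnable relative-position
    bias indexed by the (Δrow, Δcol) offset between the two tokens.
    """

    def __init__(self, rng: np.random.Generator, cfg: AttentionConfig):
        dim = cfg.channels
        self.cfg = cfg
        self.wq = Linear(rng, dim, dim, bias=False)
        self.wk = Linear(rng, dim, dim, bias=False)
        self.wv = Linear(rng, dim, dim, bias=False)
        self.proj = Linear(rng, dim, dim)
        S = cfg.window_size
        self.bias_table = Parameter(
            trunc_normal(rng, ((2 * S - 1) ** 2, cfg.num_heads), std=0.02))
        self._bias_index_full = relative_position_index(S)
        self._bias_index = self._bias_index_full.reshape(-1)

    def __call__(self, w: Tensor, mask: np.ndarray | None = None,
                 return_weights: bool = False):
        """w: (nWindows, N, C) window tokens; mask: (nWindows, N, N) additive."""
        nw, N, C = w.shape
        cfg = self.cfg
        if C != cfg.channels:
            raise ValueError(
                f"token dim {C} != num_heads*head_dim = {cfg.channels}")
        h, d = cfg.num_heads, cfg.head_dim

        def heads(t: Tensor) -> Tensor:
            return t.reshape(nw, N, h, d).transpose(0, 2, 1, 3)

        q = heads(self.wq(w))
        k = heads(self.wk(w))
        v = heads(self.wv(w))
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        # partial windows (N < S² tokens) use the leading raster positions
        idx = (self._bias_index if N == self._bias_index_full.shape[0]
               else self._bias_index_full[:N, :N].reshape(-1))
        bias = take(self.bias_table, idx)                   # (N², h)
        bias = bias.reshape(N, N, h).transpose(2, 0, 1).reshape(1, h, N, N)
        logits = logits + bias
        m = None if mask is None else mask[:, None, :, :]
        attn = softmax(logits, axis=-1, mask=m)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(nw, N, C)
        out = self.proj(out)
        if return_weights:
            return out, attn.data
        return out

    # -- full-grid application (padding, optional cyclic shift) -------------

    def forward_grid(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        S, shift = self.cfg.window_size, self.cfg.shift
        pad_h = (-H) % S
        pad_w = (-W) % S
        valid = None
        if pad_h or pad_w:
            valid = np.zeros((H + pad_h, W + pad_w), dtype=bool)
            valid[:H, :W] = True
            x = pad2d(x, (0, pad_h), (0, pad_w))
        Hp, Wp = H + pad_h, W + pad_w
        if shift:
            x = roll2d(x, -shift, -shift)
        mask = swmsa_mask(Hp, Wp, S, shift, valid)
        if mask is not None and B > 1:
            mask = np.tile(mask, (B, 1, 1))   # windows are batch-major
        windows = window_partition(x, S)
        attended = self(windows, mask=mask)
        x = window_reverse(attended, S, Hp, Wp)
        if shift:
            x = roll2d(x, shift, shift)
        if pad_h or pad_w:
            x = crop2d(x, H, W)
        return x


def wmsa(x: Tensor, attn: WindowAttention) -> Tensor:
    """Window attention on a token grid; no information crosses windows."""
    if attn.cfg.shift != 0:
        raise ValueError("wmsa requires shift = 0")
    return attn.forward_grid(x)


def swmsa(x: Tensor, attn: WindowAttention) -> Tensor:
    """Shifted-window attention: cyclic half-window shift + masked windows."""
    return attn.forward_grid(x)


# ---------------------------------------------------------------------------
# parallel attention block
# ---------------------------------------------------------------------------

class AttentionPath(Module):
    """One residual path: F' = MLP(LN(ATT(LN(F)) + F)) + (ATT(LN(F)) + F)."""

    def __init__(self, rng: np.random.Generator, dim: int, window_size: int,
                 num_heads: int, shift: int, mlp_ratio: int = 4):
        if dim % num_heads:
            raise ValueError(f"channels {dim} not divisible by {num_heads} heads")
        cfg = AttentionConfig(window_size=window_size, num_heads=num_heads,
                              head_dim=dim // num_heads, shift=shift)
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(rng, cfg)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(rng, dim, mlp_ratio)

    def __call__(self, x: Tensor) -> Tensor:
        a = self.attn.forward_grid(self.norm1(x)) + x
        return self.mlp(self.norm2(a)) + a


PA_MODES = ("parallel", "wmsa_only", "swmsa_only", "serial")


class PABlock(Module):
    """Parallel attention block: independent WMSA and SWMSA paths, summed.

    ``mode`` selects the ablation wiring: "parallel" is the full block,
    "wmsa_only"/"swmsa_only" keep a single path, and "serial" chains the
    WMSA path into the SWMSA path (the conventional alternating scheme).
    """

    def __init__(self, rng: np.random.Generator, dim: int, window_size: int,
                 num_heads: int, mlp_ratio: int = 4, mode: str = "parallel"):
        if mode not in PA_MODES:
            raise ValueError(f"unknown mode {mode!r}; valid: {PA_MODES}")
        self.mode = mode
        shift = window_size // 2
        if mode in ("parallel", "wmsa_only", "serial"):
            self.path_w = AttentionPath(rng, dim, window_size, num_heads,
                                        shift=0, mlp_ratio=mlp_ratio)
        if mode in ("parallel", "swmsa_only", "serial"):
            self.path_sw = AttentionPath(rng, dim, window_size, num_heads,
                                         shift=shift, mlp_ratio=mlp_ratio)

    def __call__(self, x: Tensor) -> Tensor:
        if self.mode == "parallel":
            return self.path_w(x) + self.path_sw(x)
        if self.mode == "wmsa_only":
            return self.path_w(x)
        if self.mode == "swmsa_only":
            return self.path_sw(x)
        return self.path_sw(self.path_w(x))


def pa_block(x: Tensor, block: PABlock) -> Tensor:
    """Apply a parallel attention block to a token grid."""
    return block(x)
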