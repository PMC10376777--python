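"""Hierarchical attention network for binary liver-ultrasound classification.

The forward pass mirrors the ventral visual pathway: a patch embedding (PE)
tokenizes the image, three stages of parallel attention (PA) blocks with
patch-merging downsampling (DS) extract features at H/4 … H/32 resolution,
center-surround inhibition (RFFE) sharpens the first stage, and upsampled
high-stage features feed back into the first-stage representation before the
classification block (CB) pools and projects to two logits:

    F0 = PE(I) [+ US(F2) + US(F3) + US(F4) on feedback passes]
    F1 = DS(PA(F0) + RFFE(F0))
    F2 = DS(PA(F1));  F3 = DS(PA(F2));  F4 = PA(F3)
    l  = CB(F4)

The feedback equation is circular (F0 depends on features computed from F0),
so it is unrolled: pass 1 runs purely feed-forward, and each subsequent pass
adds feedback computed from the previous pass.  Feedback projections are
zero-initialized, so an untrained network is exactly feed-forward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autodiff import (DEFAULT_DTYPE, Linear, Module, Parameter, Tensor,
                       bilinear_resize)
from .attention import LayerNorm, PABlock, check_finite
from .rffe import RFFE

VARIANTS = ("binet", "binet_wo_swmsa", "binet_wo_wmsa", "serial_baseline")

_VARIANT_TO_MODE = {
    "binet": "parallel",
    "binet_wo_swmsa": "wmsa_only",
    "binet_wo_wmsa": "swmsa_only",
    "serial_baseline": "serial",
}


@dataclass
class NetworkConfig:
    """Channel plan and geometry of the network.

    The full-scale plan embeds 4×4 patches of a 3-channel image into
    2·C·4·4 = 96 channels (C = 3) and doubles channels at every merge:
    96 → 192 → 384 → 768.  The desk-scale plan keeps every mechanism but
    shrinks channels so the model trains in minutes on a CPU.
    """
    input_size: int = 224
    patch_size: int = 4
    stage_channels: tuple[int, ...] = (96, 192, 384, 768)
    num_heads: tuple[int, ...] = (3, 6, 12, 24)
    window_size: int = 7
    mlp_ratio: int = 4
    num_classes: int = 2
    feedback_passes: int = 1
    detach_feedback: bool = True
    variant: str = "binet"
    # fixed input standardization (pixel range [0,1] -> [-1,1]); without it the
    # patch-embedding LayerNorm is scale-invariant and erases echogenicity
    input_mean: float = 0.5
    input_std: float = 0.5

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; valid: {VARIANTS}")
        for a, b in zip(self.stage_channels, self.stage_channels[1:]):
            if b != 2 * a:
                raise ValueError("stage channels must double at every merge")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if self.feedback_passes < 0:
            raise ValueError("feedback_passes must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        d = json.loads(text)
        d["stage_channels"] = tuple(d["stage_channels"])
        d["num_heads"] = tuple(d["num_heads"])
        return cls(**d)


def desk_config(**overrides) -> NetworkConfig:
    """Reduced configuration for CPU-scale experiments."""
    base = dict(input_size=128, window_size=4,
                stage_channels=(24, 48, 96, 192), num_heads=(3, 6, 12, 24))
    base.update(overrides)
    return NetworkConfig(**base)


@dataclass
class StageOutputs:
    """Per-stage token grids of the final pass, plus the class logits."""
    f0: Tensor
    f1: Tensor
    f2: Tensor
    f3: Tensor
    f4: Tensor
    logits: Tensor


class PatchEmbed(Module):
    """PE = LN(Flatten(Conv2D(I))): non-overlapping p×p patches projected to
    the embedding dimension, then layer-normalized per token."""

    def __init__(self, rng: np.random.Generator, patch_size: int,
                 in_channels: int, embed_dim: int):
        self.patch_size = patch_size
        self.proj = Linear(rng, patch_size * patch_size * in_channels, embed_dim)
        self.norm = LayerNorm(embed_dim, name="patch_embed")

    def __call__(self, img: Tensor) -> Tensor:
        B, H, W, C = img.shape
        p = self.patch_size
        if H % p or W % p:
            raise ValueError(f"image {H}x{W} not divisible by patch size {p}")
        x = img.reshape(B, H // p, p, W // p, p, C)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(B, H // p, W // p, p * p * C)
        return self.norm(self.proj(x))


class PatchMerging(Module):
    """DS = Linear(LN(Cat(2×2 neighborhood))): halve resolution, double channels."""

    def __init__(self, rng: np.random.Generator, dim: int):
        self.norm = LayerNorm(4 * dim, name="downsample")
        self.reduce = Linear(rng, 4 * dim, 2 * dim, bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"grid {H}x{W} must have even sides to merge")
        x = x.reshape(B, H // 2, 2, W // 2, 2, C)
        tl = x.transpose(0, 1, 3, 2, 4, 5).reshape(B, H // 2, W // 2, 4 * C)
        return self.reduce(self.norm(tl))


class FeedbackProjection(Module):
    """Upsample a high-stage grid to the F0 grid and project to F0's channels.

    Bilinear resampling (fixed, deterministic) + a 1×1 linear map that is
    zero-initialized: feedback starts as an exact no-op and is learned.
    """

    def __init__(self, in_dim: int, out_dim: int):
        self.proj = Parameter(np.zeros((in_dim, out_dim), dtype=DEFAULT_DTYPE))

    def __call__(self, x: Tensor, target_hw: tuple[int, int]) -> Tensor:
        up = bilinear_resize(x, target_hw[0], target_hw[1])
        return up @ self.proj


class ClassificationHead(Module):
    """CB = Linear(Flatten(GlobalAvgPool(LN(F4))))."""

    def __init__(self, rng: np.random.Generator, dim: int, num_classes: int):
        self.norm = LayerNorm(dim, name="classification_block")
        self.fc = Linear(rng, dim, num_classes)

    def __call__(self, x: Tensor) -> Tensor:
        pooled = self.norm(x).mean(axis=(1, 2))
        return self.fc(pooled)


class BiNet(Module):
    """The full network; see the module docstring for the dataflow."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.cfg = cfg
        ch = cfg.stage_channels
        mode = _VARIANT_TO_MODE[cfg.variant]

        self.patch_embed = PatchEmbed(rng, cfg.patch_size, 3, ch[0])
        self.rffe = RFFE(ch[0])
        self.pa1 = PABlock(rng, ch[0], cfg.window_size, cfg.num_heads[0],
                           cfg.mlp_ratio, mode)
        self.ds1 = PatchMerging(rng, ch[0])
        self.pa2 = PABlock(rng, ch[1], cfg.window_size, cfg.num_heads[1],
                           cfg.mlp_ratio, mode)
        self.ds2 = PatchMerging(rng, ch[1])
        self.pa3 = PABlock(rng, ch[2], cfg.window_size, cfg.num_heads[2],
                           cfg.mlp_ratio, mode)
        self.ds3 = PatchMerging(rng, ch[2])
        self.pa4 = PABlock(rng, ch[3], cfg.window_size, cfg.num_heads[3],
                           cfg.mlp_ratio, mode)
        self.feedback_f2 = FeedbackProjection(ch[2], ch[0])
        self.feedback_f3 = FeedbackProjection(ch[3], ch[0])
        self.feedback_f4 = FeedbackProjection(ch[3], ch[0])
        self.head = ClassificationHead(rng, ch[3], cfg.num_classes)

    # ------------------------------------------------------------------

    def _expect(self, x: Tensor, hw: int, c: int, stage: str) -> Tensor:
        B, H, W, C = x.shape
        if (H, W, C) != (hw, hw, c):
            raise ValueError(
                f"{stage}: expected grid {hw}x{hw}x{c}, got {H}x{W}x{C}")
        return check_finite(x, stage)

    def _single_pass(self, img: Tensor, feedback: Tensor | None):
        cfg = self.cfg
        n = cfg.input_size // cfg.patch_size
        ch = cfg.stage_channels

        f0 = self.patch_embed(img)
        if feedback is not None:
            f0 = f0 + feedback
        self._expect(f0, n, ch[0], "F0")
        f1 = self.ds1(self.pa1(f0) + self.rffe(f0))
        self._expect(f1, n // 2, ch[1], "F1")
        f2 = self.ds2(self.pa2(f1))
        self._expect(f2, n // 4, ch[2], "F2")
        f3 = self.ds3(self.pa3(f2))
        self._expect(f3, n // 8, ch[3], "F3")
        f4 = self.pa4(f3)
        self._expect(f4, n // 8, ch[3], "F4")
        return f0, f1, f2, f3, f4

    def feedback_sum(self, f2: Tensor, f3: Tensor, f4: Tensor) -> Tensor:
        """Σ US(F_i) for i ∈ {2,3} plus US(F4), on the F0 grid."""
        n = self.cfg.input_size // self.cfg.patch_size
        if self.cfg.detach_feedback:
            f2, f3, f4 = f2.detach(), f3.detach(), f4.detach()
        return (self.feedback_f2(f2, (n, n)) + self.feedback_f3(f3, (n, n))
                + self.feedback_f4(f4, (n, n)))

    def forward(self, img: Tensor | np.ndarray) -> StageOutputs:
        if not isinstance(img, Tensor):
            img = Tensor(img)
        if img.ndim == 3:
            img = img.reshape(1, *img.shape)
        B, H, W, C = img.shape
        if H != self.cfg.input_size or W != self.cfg.input_size or C != 3:
            raise ValueError(
                f"input: expected {self.cfg.input_size}x{self.cfg.input_size}x3, "
                f"got {H}x{W}x{C}")
        check_finite(img, "input")
        img = (img - self.cfg.input_mean) * (1.0 / self.cfg.input_std)

        feedback = None
        for p in range(self.cfg.feedback_passes + 1):
            f0, f1, f2, f3, f4 = self._single_pass(img, feedback)
            if p < self.cfg.feedback_passes:
                feedback = self.feedback_sum(f2, f3, f4)
        logits = self.head(f4)
        return StageOutputs(f0=f0, f1=f1, f2=f2, f3=f3, f4=f4, logits=logits)

    __call__ = forward


def build_variant(name: str, cfg: NetworkConfig,
                  rng: np.random.Generator | None = None) -> BiNet:
    """Construct one of the ablation variants of the network."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; valid names: {VARIANTS}")
    d = asdict(cfg)
    d["variant"] = name
    d["stage_channels"] = tuple(d["stage_channels"])
    d["num_heads"] = tuple(d["num_heads"])
    return BiNet(NetworkConfig(**d), rng=rng)


# ---------------------------------------------------------------------------
# checkpoints and inspection
# ---------------------------------------------------------------------------

def save_checkpoint(model: BiNet, path: str | Path):
    """Flat name→array archive (.npz) with a JSON config sidecar."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    path.with_suffix(".json").write_text(model.cfg.to_json())


def load_checkpoint(path: str | Path) -> BiNet:
    path = Path(path)
    cfg = NetworkConfig.from_json(path.with_suffix(".json").read_text())
    model = BiNet(cfg)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        model.load_state_dict({k: z[k] for k in z.files})
    return model


def load_matching_weights(model: BiNet, archive: str | Path) -> list[str]:
    """Optional transfer-learning hook: copy every shape-matching array from a
    user-supplied name→array archive; everything else keeps its random init."""
    with np.load(archive) as z:
        state = {k: z[k] for k in z.files}
    return model.load_state_dict(state, strict=False)


def stage_feature_maps(outputs: StageOutputs) -> dict[str, np.ndarray]:
    """Channel-mean map per stage, rescaled to uint8 (feature inspection)."""
    maps = {}
    for name in ("f0", "f1", "f2", "f3", "f4"):
        x = getattr(outputs, name).data[0].mean(axis=-1)
        lo, hi = x.min(), x.max()
        scale = 255.0 / (hi - lo) if hi > lo else 0.0
        maps[name] = ((x - lo) * scale).astype(np.uint8)
    return maps
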