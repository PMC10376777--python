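"""Synthetic B-mode liver phantoms with speckle, plus split/augmentation protocol.

The generator emulates the two diagnostic appearances the classifier must
separate.  A *fatty* liver is hyperechoic ("bright liver"): high near-field
brightness, depth attenuation of the beam (the far field darkens), and
blurred, low-contrast vessel walls.  A *normal* liver is mid-gray with
negligible attenuation and crisp, dark vessels.  Both classes are corrupted
by multiplicative speckle — the squared magnitude of a locally correlated
complex Gaussian field (a first-order surrogate for fully developed
ultrasound speckle).

Images are generated at 720×480 (width × height), 8-bit, 3 identical
channels, and resized to the network input at load time.  Datasets are split
4:1 into train/validation vs. test *before* augmentation, and only the
train/validation pool is augmented, so no derivative of a test image can
leak into training.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

LABELS = ("normal", "fatty")

DEFAULT_AUGMENT_SPEC = {
    "rotations": [30, 75, 135, 225],
    "scale_range": (0.8, 1.2),
    "flips": True,
}

# Class-conditional parameter ranges (chosen once; see docs/methods.md).
_PARAM_RANGES = {
    "normal": dict(base_echo=(0.30, 0.45), atten_slope=(0.0, 0.10),
                   vessel_contrast=(0.35, 0.55), vessel_blur=(0.5, 1.5)),
    "fatty": dict(base_echo=(0.60, 0.80), atten_slope=(0.30, 0.70),
                  vessel_contrast=(0.08, 0.20), vessel_blur=(4.0, 8.0)),
}
_VESSEL_COUNT = (3, 7)          # inclusive-exclusive
_SPECKLE_RANGE = (0.5, 0.9)
_SPECKLE_CORR_SIGMA = 1.2       # px; lateral correlation of the speckle field


@dataclass
class PhantomParams:
    """Parameters of one synthetic B-mode image (deterministic given seed)."""
    label: str
    size: tuple[int, int] = (720, 480)          # (width, height)
    base_echo: float = 0.4
    atten_slope: float = 0.0
    vessel_count: int = 4
    vessel_contrast: float = 0.4
    vessel_blur: float = 1.0
    speckle_scale: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if min(self.size) < 16:
            raise ValueError("size too small")
        if not (0 <= self.base_echo <= 1 and 0 <= self.vessel_contrast <= 1):
            raise ValueError("echo/contrast parameters must lie in [0, 1]")
        if self.atten_slope < 0 or self.vessel_blur < 0 or self.speckle_scale < 0:
            raise ValueError("scales must be non-negative")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be non-negative")


def sample_params(label: str, seed: int, size: tuple[int, int] = (720, 480)) -> PhantomParams:
    """Draw class-conditional parameters for one phantom."""
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}")
    rng = np.random.default_rng(seed)
    r = _PARAM_RANGES[label]
    return PhantomParams(
        label=label, size=size,
        base_echo=float(rng.uniform(*r["base_echo"])),
        atten_slope=float(rng.uniform(*r["atten_slope"])),
        vessel_count=int(rng.integers(*_VESSEL_COUNT)),
        vessel_contrast=float(rng.uniform(*r["vessel_contrast"])),
        vessel_blur=float(rng.uniform(*r["vessel_blur"])),
        speckle_scale=float(rng.uniform(*_SPECKLE_RANGE)),
        seed=seed)


def _vessel_mask(rng: np.random.Generator, shape: tuple[int, int],
                 count: int) -> np.ndarray:
    """Dark elongated structures: smoothed random walks of varying thickness."""
    H, W = shape
    mask = np.zeros(shape, dtype=np.float32)
    for _ in range(count):
        r = rng.uniform(0.15, 0.85) * H
        c = rng.uniform(0.05, 0.95) * W
        angle = rng.uniform(0, 2 * np.pi)
        length = int(rng.uniform(0.25, 0.6) * min(H, W))
        thickness = int(rng.integers(3, 9))
        for _ in range(length):
            angle += rng.normal(0, 0.08)
            r += np.sin(angle)
            c += np.cos(angle)
            ri, ci = int(r), int(c)
            if not (0 <= ri < H and 0 <= ci < W):
                break
            r0, r1 = max(0, ri - thickness // 2), min(H, ri + thickness // 2 + 1)
            c0, c1 = max(0, ci - thickness // 2), min(W, ci + thickness // 2 + 1)
            mask[r0:r1, c0:c1] = 1.0
    return mask


def _speckle_field(rng: np.random.Generator, shape: tuple[int, int],
                   scale: float) -> np.ndarray:
    """Mean-one multiplicative speckle: |smoothed complex Gaussian|², blended
    toward 1 by ``scale`` (scale→0 gives a constant field)."""
    if scale == 0:
        return np.ones(shape, dtype=np.float32)
    re = ndimage.gaussian_filter(rng.standard_normal(shape), _SPECKLE_CORR_SIGMA)
    im = ndimage.gaussian_filter(rng.standard_normal(shape), _SPECKLE_CORR_SIGMA)
    intensity = re ** 2 + im ** 2
    intensity /= intensity.mean()
    return np.clip(1.0 + scale * (intensity - 1.0), 0.0, None).astype(np.float32)


def generate_phantom(p: PhantomParams) -> np.ndarray:
    """Render one phantom as an (H, W, 3) uint8 image; deterministic given seed."""
    W, H = p.size
    rng = np.random.default_rng(p.seed)

    depth = np.linspace(0.0, 1.0, H, dtype=np.float32)[:, None]
    field = p.base_echo * np.exp(-p.atten_slope * depth)
    field = np.broadcast_to(field, (H, W)).copy()

    if p.vessel_count > 0:
        mask = _vessel_mask(rng, (H, W), p.vessel_count)
        if p.vessel_blur > 0:
            # blurring spreads and dilutes the vessel walls: the fatty cue
            mask = ndimage.gaussian_filter(mask, p.vessel_blur)
        field = field * (1.0 - p.vessel_contrast * np.clip(mask, 0.0, 1.0))

    img = field * _speckle_field(rng, (H, W), p.speckle_scale)
    img8 = (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    return np.repeat(img8[:, :, None], 3, axis=2)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _rescale_about_center(img: np.ndarray, scale: float) -> np.ndarray:
    """Isotropic zoom keeping the output size; reflect-pad when shrinking."""
    if scale == 1.0:
        return img
    H, W = img.shape[:2]
    z = ndimage.zoom(img, (scale, scale, 1), order=1)
    h, w = z.shape[:2]
    if h >= H:
        top, left = (h - H) // 2, (w - W) // 2
        return z[top:top + H, left:left + W]
    ph, pw = H - h, W - w
    return np.pad(z, ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2), (0, 0)),
                  mode="reflect")


def apply_augment(img: np.ndarray, rotation: float = 0.0, scale: float = 1.0,
                  hflip: bool = False, vflip: bool = False) -> np.ndarray:
    """One augmentation op: scale, rotate (reflect padding), then flips.

    Identity parameters return the input unchanged, bit for bit.  Rotations
    that are multiples of 90° are exact; others use bilinear interpolation.
    """
    out = img
    out = _rescale_about_center(out, float(scale))
    rot = float(rotation) % 360.0
    if rot != 0.0:
        if rot % 90.0 == 0.0:
            out = np.rot90(out, k=int(rot // 90), axes=(0, 1))
            if out.shape != img.shape:   # non-square: fall back to resampling
                out = ndimage.rotate(img, rot, axes=(1, 0), reshape=False,
                                     order=1, mode="reflect")
        else:
            out = ndimage.rotate(out, rot, axes=(1, 0), reshape=False,
                                 order=1, mode="reflect")
    if hflip:
        out = out[:, ::-1]
    if vflip:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def augment(img: np.ndarray, ops_spec: dict | None = None, seed: int = 0) -> list:
    """Produce one augmented image per configured rotation angle.

    Each output combines its rotation with a random isotropic scale and
    random horizontal/vertical flips; deterministic given ``seed``.
    Returns ``[(op_string, image), ...]``.
    """
    spec = dict(DEFAULT_AUGMENT_SPEC if ops_spec is None else ops_spec)
    rng = np.random.default_rng(seed)
    out = []
    for angle in spec.get("rotations", [0]):
        lo, hi = spec.get("scale_range", (1.0, 1.0))
        scale = float(rng.uniform(lo, hi))
        hflip = bool(rng.integers(2)) if spec.get("flips", False) else False
        vflip = bool(rng.integers(2)) if spec.get("flips", False) else False
        op = f"rot={angle};scale={scale:.4f};hflip={int(hflip)};vflip={int(vflip)}"
        out.append((op, apply_augment(img, angle, scale, hflip, vflip)))
    return out


def _parse_ops(op: str) -> dict:
    if not op or op == "base":
        return {}
    kv = dict(item.split("=") for item in op.split(";"))
    return dict(rotation=float(kv["rot"]), scale=float(kv["scale"]),
                hflip=bool(int(kv["hflip"])), vflip=bool(int(kv["vflip"])))


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("path", "label", "split", "seed", "ops")


def make_dataset(n_normal: int, n_fatty: int, split_ratio: tuple[int, int] = (4, 1),
                 augment_spec: dict | None = None, seed: int = 0,
                 root: str | Path | None = None,
                 size: tuple[int, int] = (720, 480)) -> pd.DataFrame:
    """Generate a two-class phantom dataset manifest (and optionally the PNGs).

    Base images are split ``split_ratio`` into trainval/test per class
    *before* augmentation; augmented derivatives are created only for
    trainval rows.  With ``root`` given, PNGs and ``manifest.csv`` are
    written there; otherwise the manifest alone is returned and images can
    be rendered on demand with :func:`render_row`.
    """
    if n_normal < 1 or n_fatty < 1:
        raise ValueError("need at least one image per class")
    denom = split_ratio[0] + split_ratio[1]
    rng = np.random.default_rng(seed)
    rows = []
    for label, n in (("normal", n_normal), ("fatty", n_fatty)):
        n_test = round(n * split_ratio[1] / denom)
        if n_test < 1 or n - n_test < 1:
            raise ValueError(
                f"split ratio {split_ratio} infeasible for {n} {label} images")
        splits = np.array(["trainval"] * (n - n_test) + ["test"] * n_test)
        rng.shuffle(splits)
        for i, split in enumerate(splits):
            img_seed = int(rng.integers(2 ** 31))
            rows.append(dict(path=f"{label}_{i:04d}.png", label=label,
                             split=split, seed=img_seed, ops="base"))

    if augment_spec is not None:
        aug_rows = []
        for row in rows:
            if row["split"] != "trainval":
                continue
            base = generate_phantom(sample_params(row["label"], row["seed"], size))
            for j, (op, img) in enumerate(augment(base, augment_spec,
                                                  seed=row["seed"] + 1)):
                aug_rows.append(dict(
                    path=row["path"].replace(".png", f"_aug{j}.png"),
                    label=row["label"], split="trainval",
                    seed=row["seed"], ops=op, _img=img))
        rows.extend(aug_rows)

    manifest = pd.DataFrame(rows)
    if root is not None:
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        for row in rows:
            img = row.pop("_img", None)
            if img is None:
                img = generate_phantom(sample_params(row["label"], row["seed"], size))
            Image.fromarray(img).save(root / row["path"])
        manifest = manifest[list(MANIFEST_COLUMNS)]
        manifest.to_csv(root / "manifest.csv", index=False)
    else:
        manifest = manifest.drop(columns=["_img"], errors="ignore")
    return manifest[list(MANIFEST_COLUMNS)].copy()


def render_row(row, size: tuple[int, int] = (720, 480),
               root: str | Path | None = None) -> np.ndarray:
    """Materialize one manifest row: read its PNG if present, else regenerate
    it from the recorded seed and augmentation ops."""
    if root is not None:
        path = Path(root) / row["path"]
        if path.exists():
            return np.asarray(Image.open(path).convert("RGB"))
    img = generate_phantom(sample_params(row["label"], int(row["seed"]), size))
    ops = _parse_ops(row["ops"])
    if ops:
        img = apply_augment(img, **ops)
    return img


def load_split(manifest: pd.DataFrame, split: str, input_size: int,
               root: str | Path | None = None,
               size: tuple[int, int] = (720, 480)):
    """Load one split as (images, labels): float32 (N, s, s, 3) in [0, 1] and
    int labels (fatty = 1, the positive class)."""
    part = manifest[manifest["split"] == split]
    if len(part) == 0:
        raise ValueError(f"split {split!r} is empty")
    xs, ys = [], []
    for _, row in part.iterrows():
        img = render_row(row, size=size, root=root)
        pil = Image.fromarray(img).resize((input_size, input_size), Image.BILINEAR)
        xs.append(np.asarray(pil, dtype=np.float32) / 255.0)
        ys.append(1 if row["label"] == "fatty" else 0)
    return np.stack(xs), np.asarray(ys, dtype=np.int64)
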