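"""Receptive-field feature extraction: center-surround inhibition.

Neurons in the primary visual cortex respond to stimulation of their
classical receptive field (CRF) and are suppressed by simultaneous
stimulation of the non-classical surround (nCRF).  Classically this is
modelled with a difference-of-Gaussians (DoG) kernel whose surround scale is
twice the center scale:

    DoG_σ(x, y) = N(0, (2σ)²)(x, y) − N(0, σ²)(x, y)

Here the suppression is realized with small trainable convolutions:

    nCRF(x)   = C5×5(C5×5(x)) − C3×3(C3×3(x))
    CRF(x)    = C3×3(x)
    Output(x) = CRF(x) − nCRF(x)

All convolutions are depthwise (per channel), zero-padded 'same', bias-free
and purely linear — no activation or normalization follows.  Kernels are
initialized from the discretized DoG so training starts from the biological
prior; a trainable 1×1 channel mix (identity-initialized) follows the
difference so the module can exchange information across channels while
staying shape-compatible with the token grid it is applied to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import DEFAULT_DTYPE, Module, Parameter, Tensor, depthwise_conv2d


@dataclass
class DoGParams:
    """Center scale σ of the DoG; the surround scale is fixed at 2σ."""
    sigma: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def dog_weight(x: float, y: float, p: DoGParams) -> float:
    """Difference-of-Gaussians weight at offset (x, y).

    Surround minus center: (1/(2π·4σ²))e^{−r²/(2·4σ²)} − (1/(2πσ²))e^{−r²/(2σ²)}.
    """
    if p.sigma <= 0:
        raise ValueError("sigma must be positive")
    r2 = np.asarray(x, dtype=np.float64) ** 2 + np.asarray(y, dtype=np.float64) ** 2
    s2 = p.sigma ** 2
    surround = np.exp(-r2 / (2.0 * 4.0 * s2)) / (2.0 * np.pi * 4.0 * s2)
    center = np.exp(-r2 / (2.0 * s2)) / (2.0 * np.pi * s2)
    return surround - center


def discretize_dog(p: DoGParams, size: int) -> np.ndarray:
    """Sample the DoG on a size×size grid centred at the origin (unit spacing)."""
    if size < 1 or size % 2 == 0:
        raise ValueError("kernel size must be an odd positive integer")
    half = size // 2
    xs = np.arange(-half, half + 1, dtype=np.float64)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    return dog_weight(X, Y, p).astype(np.float64)


def balanced_dog(p: DoGParams, size: int) -> np.ndarray:
    """Zero-sum discrete DoG: each sampled Gaussian is normalized to unit sum
    on the truncated grid before differencing.  The raw samples of
    :func:`discretize_dog` lose surround mass to truncation at small sizes;
    renormalizing restores the zero-DC (constant-suppressing) property."""
    if size < 1 or size % 2 == 0:
        raise ValueError("kernel size must be an odd positive integer")
    half = size // 2
    xs = np.arange(-half, half + 1, dtype=np.float64)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    r2 = X ** 2 + Y ** 2
    surround = np.exp(-r2 / (2.0 * (2.0 * p.sigma) ** 2))
    center = np.exp(-r2 / (2.0 * p.sigma ** 2))
    return surround / surround.sum() - center / center.sum()


def _depthwise_init(kernel2d: np.ndarray, channels: int) -> np.ndarray:
    return np.repeat(kernel2d[:, :, None], channels, axis=2).astype(DEFAULT_DTYPE)


class RffeWeights(Module):
    """Trainable kernels of the inhibition module (all depthwise, bias-free).

    Initialized from the zero-sum discrete DoG so training starts from a
    surround-suppressing prior with no DC response."""

    def __init__(self, channels: int, sigma: float = 1.0):
        dog3 = balanced_dog(DoGParams(sigma), 3)
        dog5 = balanced_dog(DoGParams(sigma), 5)
        self.k5_outer = Parameter(_depthwise_init(dog5, channels))
        self.k5_inner = Parameter(_depthwise_init(dog5, channels))
        self.k3_surround_a = Parameter(_depthwise_init(dog3, channels))
        self.k3_surround_b = Parameter(_depthwise_init(dog3, channels))
        self.k3_crf = Parameter(_depthwise_init(dog3, channels))


def ncrf_response(x: Tensor, w: RffeWeights) -> Tensor:
    """Surround response: C5×5(C5×5(x)) − C3×3(C3×3(x)), 'same' padding."""
    wide = depthwise_conv2d(depthwise_conv2d(x, w.k5_inner), w.k5_outer)
    narrow = depthwise_conv2d(depthwise_conv2d(x, w.k3_surround_a), w.k3_surround_b)
    return wide - narrow


def crf_response(x: Tensor, w: RffeWeights) -> Tensor:
    """Center response: a single 3×3 'same' convolution."""
    return depthwise_conv2d(x, w.k3_crf)


def rffe_forward(x: Tensor, w: RffeWeights) -> Tensor:
    """Inhibited response: CRF(x) − nCRF(x).  Purely linear, shape-preserving."""
    return crf_response(x, w) - ncrf_response(x, w)


class RFFE(Module):
    """Inhibition module as used inside the network: depthwise center-surround
    filtering of the token grid followed by a 1×1 channel mix."""

    def __init__(self, channels: int, sigma: float = 1.0):
        self.weights = RffeWeights(channels, sigma=sigma)
        self.channel_mix = Parameter(np.eye(channels, dtype=DEFAULT_DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return rffe_forward(x, self.weights) @ self.channel_mix
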