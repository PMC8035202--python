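"""V1/V2-level front end: oriented energy filtering and local max pooling.

Layers 1-2 of the shallow network. An RGB image is converted to a 7-channel
ChannelStack: phase-invariant Gabor edge energy at four orientations computed
on luminance, plus max-pooled red, green and blue intensity. Orientation
channels are normalized by the bank's maximum attainable response to a
unit-contrast step edge so that orientation and color live on comparable
scales.

Channel angles label the *edge* orientation (degrees from horizontal): a
vertical luminance edge drives the 90-degree channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.filters import gabor_kernel
from sklearn.base import BaseEstimator, TransformerMixin

from .types import (
    FRAGMENT_SIZE_MAX,
    FRAGMENT_SIZE_MIN,
    ChannelStack,
    FeatureCandidate,
    ORIENTATIONS_DEG,
)

__all__ = [
    "GaborBank",
    "V1V2FrontEnd",
    "preprocess",
    "local_max_pool",
    "extract_fragments",
]


@dataclass
class GaborBank:
    """Quadrature Gabor bank: one spatial frequency, four orientations.

    frequency is in cycles/pixel; sigma is the isotropic Gaussian envelope
    width in pixels. With the defaults the kernel support is 11x11 pixels,
    matched to 200-pixel stimuli.
    """

    frequency: float = 0.25
    sigma: float = 1.8
    n_stds: float = 3.0
    _kernels: dict = field(default_factory=dict, repr=False, compare=False)
    _edge_norms: dict = field(default_factory=dict, repr=False, compare=False)

    def kernel(self, angle_deg: float) -> np.ndarray:
        """Complex kernel whose energy responds to edges oriented at
        ``angle_deg``. The carrier runs perpendicular to the edge."""
        if angle_deg not in self._kernels:
            theta = math.radians((angle_deg + 90.0) % 180.0)
            k = gabor_kernel(
                self.frequency,
                theta=theta,
                sigma_x=self.sigma,
                sigma_y=self.sigma,
                n_stds=self.n_stds,
            )
            # zero-mean even part: no response to uniform luminance
            re = np.real(k) - np.real(k).mean()
            self._kernels[angle_deg] = re + 1j * np.imag(k)
        return self._kernels[angle_deg]

    @property
    def support(self) -> int:
        """Kernel side length in pixels."""
        return self.kernel(0).shape[0]

    def energy(self, gray: np.ndarray, angle_deg: float) -> np.ndarray:
        """Phase-invariant oriented energy (root-sum-square of quadrature
        pair), reflect-padded so output size equals input size."""
        k = self.kernel(angle_deg)
        re = ndimage.convolve(gray, np.real(k), mode="reflect")
        im = ndimage.convolve(gray, np.imag(k), mode="reflect")
        return np.sqrt(re * re + im * im)

    def edge_norm(self, angle_deg: float) -> float:
        """Maximum energy the bank attains on a unit-contrast step edge at
        ``angle_deg``; used to normalize orientation channels."""
        if angle_deg not in self._edge_norms:
            n = 8 * self.support + 1
            yy, xx = np.mgrid[0:n, 0:n].astype(float)
            c = (n - 1) / 2.0
            # step perpendicular to the edge direction
            normal = math.radians((angle_deg + 90.0) % 180.0)
            proj = (xx - c) * math.cos(normal) + (yy - c) * math.sin(normal)
            step = (proj > 0).astype(float)
            inner = self.energy(step, angle_deg)[
                self.support : -self.support, self.support : -self.support
            ]
            self._edge_norms[angle_deg] = float(inner.max())
        return self._edge_norms[angle_deg]


def local_max_pool(arr: np.ndarray, window: int, stride: int) -> np.ndarray:
    """Max-pool a 2-D map.

    Each output cell (i, j) is the maximum of the input block
    ``[i*stride : i*stride + window, j*stride : j*stride + window]``
    intersected with the map, so border cells pool over the valid
    intersection. Output size is ``ceil(H/stride) x ceil(W/stride)``.
    """
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D map")
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1")
    h, w = arr.shape
    oh = -(-h // stride)
    ow = -(-w // stride)
    if oh < 1 or ow < 1:
        raise ValueError("no valid pooled cell")
    out = np.empty((oh, ow), dtype=float)
    for i in range(oh):
        r0 = i * stride
        r1 = min(r0 + window, h)
        block_rows = arr[r0:r1]
        for j in range(ow):
            c0 = j * stride
            c1 = min(c0 + window, w)
            out[i, j] = block_rows[:, c0:c1].max()
    return out


def preprocess(
    image: np.ndarray,
    bank: GaborBank | None = None,
    pool_window: int = 10,
    pool_stride: int = 10,
) -> ChannelStack:
    """Convert an RGB image to its 7-channel V1/V2-level representation.

    Orientation channels: Gabor energy on luminance at 0/45/90/135 degrees,
    normalized by the bank's maximum step-edge response, then max-pooled.
    Color channels: max-pooled raw R, G, B intensities in [0, 1].
    """
    bank = bank or GaborBank()
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if min(image.shape[:2]) < bank.support:
        raise ValueError(
            f"image smaller than the {bank.support}-px filter support"
        )
    gray = rgb2gray(image)
    channels = []
    for ang in ORIENTATIONS_DEG:
        e = bank.energy(gray, ang) / bank.edge_norm(ang)
        channels.append(local_max_pool(e, pool_window, pool_stride))
    for c in range(3):
        channels.append(local_max_pool(image[:, :, c], pool_window, pool_stride))
    return ChannelStack(np.stack(channels), grid_stride_px=pool_stride)


def extract_fragments(
    stack: ChannelStack,
    sizes: Sequence[int],
    stride: int,
    seed: int,
    max_count: int,
    source_image_id: str = "src",
    scale_range_b: Sequence[float] = (0.8, 1.0, 1.25),
) -> list[FeatureCandidate]:
    """Cut square fragment candidates from a preprocessed source image.

    Windows are enumerated on the stride grid for each size; if the
    enumeration exceeds ``max_count`` a seeded uniform subsample (without
    replacement, enumeration order preserved) is returned.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = stack.shape
    for size in sizes:
        if not (FRAGMENT_SIZE_MIN <= size <= FRAGMENT_SIZE_MAX):
            raise ValueError(
                f"fragment size {size} outside "
                f"[{FRAGMENT_SIZE_MIN}, {FRAGMENT_SIZE_MAX}]"
            )
        if size > h or size > w:
            raise ValueError(f"stack {h}x{w} smaller than fragment size {size}")
    windows: list[tuple[int, int, int]] = []
    for size in sizes:
        for r0 in range(0, h - size + 1, stride):
            for c0 in range(0, w - size + 1, stride):
                windows.append((size, r0, c0))
    if len(windows) > max_count:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(windows), size=max_count, replace=False)
        windows = [windows[i] for i in sorted(keep)]
    out = []
    for size, r0, c0 in windows:
        out.append(
            FeatureCandidate(
                candidate_id=f"{source_image_id}:s{size}:r{r0}:c{c0}",
                stack=stack.window(r0, c0, size, size),
                source_image_id=source_image_id,
                source_window=(r0, c0, size, size),
                scale_range_b=tuple(scale_range_b),
            )
        )
    return out


class V1V2FrontEnd(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer wrapping :func:`preprocess`.

    ``transform`` maps a list of RGB images to a list of ChannelStacks.
    """

    def __init__(
        self,
        frequency: float = 0.25,
        sigma: float = 1.8,
        pool_window: int = 10,
        pool_stride: int = 10,
    ):
        self.frequency = frequency
        self.sigma = sigma
        self.pool_window = pool_window
        self.pool_stride = pool_stride

    def _bank(self) -> GaborBank:
        return GaborBank(frequency=self.frequency, sigma=self.sigma)

    def fit(self, X=None, y=None):
        self.bank_ = self._bank()
        return self

    def transform(self, X) -> list[ChannelStack]:
        bank = getattr(self, "bank_", None) or self._bank()
        return [
            preprocess(img, bank, self.pool_window, self.pool_stride) for img in X
        ]
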