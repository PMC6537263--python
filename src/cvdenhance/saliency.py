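"""Bottom-up saliency from the spatial density of local keypoints.

A saliency map is computed independently on each CIE L*a*b* channel —
multi-scale difference-of-Gaussians (DoG) keypoints are detected, a
Gaussian kernel density is evaluated over their locations — and the
three channel maps are averaged and renormalized to [0, 1].

The detector parameters (contrast threshold, number of scales, channel
prescaling) are declared defaults, exposed through :class:`SaliencyConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from cvdenhance.colorspace import ColorSpaceDef, EncodedImage, SRGB_D65, rgb_to_lab

__all__ = [
    "Keypoint",
    "SaliencyConfig",
    "SaliencyMap",
    "default_bandwidth",
    "detect_keypoints",
    "keypoint_density",
    "lab_saliency",
]


@dataclass(frozen=True)
class Keypoint:
    """A local DoG extremum: subpixel location, scale and response."""

    x: float
    y: float
    scale: float
    response: float


@dataclass(frozen=True)
class SaliencyMap:
    """Single-channel raster in [0, 1]; all-zero iff no keypoints fired."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError(f"saliency map must be 2-D, got shape {v.shape}")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class SaliencyConfig:
    """Parameters of the keypoint-density saliency backend."""

    contrast_threshold: float = 0.01
    n_scales: int = 8
    sigma0: float = 1.6
    scale_ratio: float = 2.0 ** 0.5
    bandwidth_frac: float = 0.05  # of the image diagonal
    ab_scale: float = 1.0 / 128.0  # prescale of a*/b* before detection
    l_scale: float = 1.0 / 100.0


def default_bandwidth(shape: tuple[int, int], frac: float = 0.05) -> float:
    """Density bandwidth as a fraction of the image diagonal."""
    h, w = shape
    return frac * float(np.hypot(h, w))


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if hi - lo <= 0.0:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def detect_keypoints(
    channel: np.ndarray,
    *,
    config: SaliencyConfig = SaliencyConfig(),
    rescale: bool = True,
) -> list[Keypoint]:
    """Deterministic multi-scale DoG extrema of a single-channel raster.

    The channel is min–max rescaled to [0, 1] first (disable with
    ``rescale=False`` when the caller has already normalized the scale, as
    :func:`lab_saliency` does).  Extrema are local maxima or minima of the
    DoG stack across space and scale whose absolute response exceeds the
    contrast threshold.  A constant channel yields no keypoints.
    """
    ch = np.asarray(channel, dtype=np.float64)
    if ch.ndim != 2:
        raise ValueError(f"expected a 2-D channel, got shape {ch.shape}")
    if not np.all(np.isfinite(ch)):
        raise ValueError("channel contains non-finite values")
    if ch.size == 0:
        return []
    if rescale:
        rng = float(ch.max()) - float(ch.min())
        if rng <= 0.0:
            return []
        ch = (ch - ch.min()) / rng
    elif float(ch.max()) == float(ch.min()):
        return []

    sigmas = config.sigma0 * config.scale_ratio ** np.arange(config.n_scales + 1)
    blurred = [ndimage.gaussian_filter(ch, s, mode="reflect") for s in sigmas]
    dog = np.stack([b1 - b0 for b0, b1 in zip(blurred, blurred[1:])])

    # 3x3x3 extrema over (scale, y, x); border scales excluded
    maxf = ndimage.maximum_filter(dog, size=3, mode="nearest")
    minf = ndimage.minimum_filter(dog, size=3, mode="nearest")
    is_ext = ((dog == maxf) | (dog == minf)) & (
        np.abs(dog) >= config.contrast_threshold
    )
    is_ext[0] = False
    is_ext[-1] = False

    points: list[Keypoint] = []
    for s_idx, yy, xx in zip(*np.nonzero(is_ext)):
        points.append(
            Keypoint(
                x=float(xx),
                y=float(yy),
                scale=float(sigmas[s_idx]),
                response=float(dog[s_idx, yy, xx]),
            )
        )
    return points


def keypoint_density(
    points: Sequence[Keypoint],
    shape: tuple[int, int],
    bandwidth: float,
    *,
    weighted: bool = False,
) -> SaliencyMap:
    """Gaussian kernel density of keypoint locations on the pixel grid.

    Exact (non-truncated) kernel sums, evaluated separably per keypoint;
    min–max normalized.  An empty keypoint list yields an all-zero map.
    By default keypoints are unweighted (pure spatial distribution);
    ``weighted=True`` scales each kernel by ``|response|``.
    """
    if bandwidth <= 0.0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    h, w = shape
    if not points:
        return SaliencyMap(np.zeros((h, w)))
    ys = np.arange(h, dtype=np.float64)
    xs = np.arange(w, dtype=np.float64)
    inv2b2 = 1.0 / (2.0 * bandwidth**2)
    py = np.array([p.y for p in points])
    px = np.array([p.x for p in points])
    wts = (
        np.abs([p.response for p in points]) if weighted else np.ones(len(points))
    )
    col = np.exp(-((ys[np.newaxis, :] - py[:, np.newaxis]) ** 2) * inv2b2)
    row = np.exp(-((xs[np.newaxis, :] - px[:, np.newaxis]) ** 2) * inv2b2)
    density = np.einsum("k,kh,kw->hw", wts, col, row)
    return SaliencyMap(_minmax(density))


def lab_saliency(
    img: EncodedImage,
    space: ColorSpaceDef = SRGB_D65,
    *,
    bandwidth: float | None = None,
    config: SaliencyConfig = SaliencyConfig(),
) -> SaliencyMap:
    """Keypoint-density saliency averaged over the L*, a*, b* channels.

    Each channel is prescaled to a comparable numeric range (L* by 1/100,
    a*/b* by 1/128) so the shared contrast threshold applies uniformly;
    the three per-channel density maps are averaged and renormalized.
    """
    lab = rgb_to_lab(img, space).pixels
    h, w = lab.shape[:2]
    if bandwidth is None:
        bandwidth = default_bandwidth((h, w), config.bandwidth_frac)
    channels = (
        lab[..., 0] * config.l_scale,
        lab[..., 1] * config.ab_scale,
        lab[..., 2] * config.ab_scale,
    )
    maps = []
    for name, ch in zip("Lab", channels):
        pts = detect_keypoints(ch, config=config, rescale=False)
        maps.append(keypoint_density(pts, (h, w), bandwidth).values)
    mean = np.mean(maps, axis=0)
    return SaliencyMap(_minmax(mean), provenance="mean(L*,a*,b*)")


#: Signature of a pluggable saliency backend.
SaliencyBackend = Callable[[EncodedImage], SaliencyMap]
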