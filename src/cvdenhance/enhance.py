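"""Saliency-guided segmentation and recoloring pipeline.

The chain, for an input image and a chosen dichromacy:

1. simulate the dichromatic view of the image;
2. compute keypoint-density saliency of both versions and their
   normalized absolute difference (the *saliency error*);
3. weight the per-channel L*a*b* difference between original and
   simulated image by the saliency error;
4. convert the weighted difference to the (linear) RGB domain, apply the
   correction vector, average channel magnitudes into a single map;
5. smooth with a 3×3 Gaussian, threshold with Otsu's method;
6. inside the resulting mask, negate a* and b* of the *original* image
   (a 180° rotation of the chroma plane; L* is untouched) and convert
   back to encoded RGB.

When original and simulated views coincide (e.g., an achromatic image)
the correction signal is numerically negligible; a degeneracy guard then
produces an all-zero map, an empty mask, and an identity enhancement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from cvdenhance.colorspace import (
    CIE_CONSTANTS,
    ColorSpaceDef,
    EncodedImage,
    LabImage,
    SRGB_D65,
    _lab_f_inverse,
    build_rgb_to_xyz_matrix,
    lab_to_rgb,
    rgb_to_lab,
)
from cvdenhance.cvd_sim import DeficiencyType, simulate_dichromacy
from cvdenhance.saliency import SaliencyConfig, SaliencyMap, lab_saliency

__all__ = [
    "CorrectionVector",
    "EnhanceConfig",
    "EnhancedResult",
    "SaliencyErrorMap",
    "SegmentationMask",
    "collapse_to_map",
    "enhance_image",
    "otsu_mask",
    "otsu_mask_tiled",
    "recolor_mask",
    "saliency_error",
    "smooth_3x3",
    "weighted_difference",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SaliencyErrorMap:
    """Normalized |difference| of two saliency maps, in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError(f"error map must be 2-D, got shape {v.shape}")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class CorrectionVector:
    """Nonnegative per-channel weights applied before channel averaging."""

    w_r: float = 1.0
    w_g: float = 1.0
    w_b: float = 1.0

    def __post_init__(self) -> None:
        w = (self.w_r, self.w_g, self.w_b)
        if not all(np.isfinite(w)) or any(x < 0.0 for x in w):
            raise ValueError(f"correction weights must be finite and >= 0, got {w}")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.w_r, self.w_g, self.w_b])


@dataclass(frozen=True)
class SegmentationMask:
    """Boolean raster of pixels above the Otsu threshold."""

    values: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=bool)
        if v.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {v.shape}")
        object.__setattr__(self, "values", v)

    @property
    def area(self) -> int:
        return int(np.count_nonzero(self.values))


@dataclass(frozen=True)
class EnhancedResult:
    enhanced: EncodedImage
    mask: SegmentationMask
    error_map: SaliencyErrorMap
    simulated_view: EncodedImage | None = None
    debug: dict = field(default_factory=dict)


@dataclass(frozen=True)
class EnhanceConfig:
    """Knobs of the enhancement pipeline (all declared defaults)."""

    correction: CorrectionVector = CorrectionVector()
    saliency: SaliencyConfig = SaliencyConfig()
    gaussian_sigma: float = 0.85
    #: pre-normalization peak below which the collapse map is treated as
    #: pure numerical noise (no chromatic information lost → no mask)
    degenerate_eps: float = 1e-3
    #: drop mask components smaller than this fraction of image area (0 = off)
    min_component_frac: float = 0.0
    #: "global" (default) or "tiled" Otsu segmentation
    otsu_mode: str = "global"
    otsu_tiles: tuple[int, int] = (4, 4)
    render_simulated_view: bool = True

    def __post_init__(self) -> None:
        if self.otsu_mode not in ("global", "tiled"):
            raise ValueError(f"otsu_mode must be 'global' or 'tiled', got {self.otsu_mode!r}")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def saliency_error(s_orig: SaliencyMap, s_sim: SaliencyMap) -> SaliencyErrorMap:
    """Normalized absolute difference of two saliency maps.

    Identical (or numerically indistinguishable) maps yield all zeros
    rather than an amplified noise floor.
    """
    if s_orig.shape != s_sim.shape:
        raise ValueError(f"shape mismatch: {s_orig.shape} vs {s_sim.shape}")
    diff = np.abs(s_orig.values - s_sim.values)
    peak = float(diff.max()) if diff.size else 0.0
    if peak <= 1e-9:
        return SaliencyErrorMap(np.zeros_like(diff))
    return SaliencyErrorMap(diff / peak)


def weighted_difference(
    lab_orig: LabImage, lab_sim: LabImage, err: SaliencyErrorMap
) -> np.ndarray:
    """Per-channel signed L*a*b* difference, weighted by the saliency error."""
    if lab_orig.pixels.shape != lab_sim.pixels.shape:
        raise ValueError(
            f"shape mismatch: {lab_orig.pixels.shape} vs {lab_sim.pixels.shape}"
        )
    if err.values.shape != lab_orig.pixels.shape[:2]:
        raise ValueError(
            f"error map shape {err.values.shape} does not match image "
            f"{lab_orig.pixels.shape[:2]}"
        )
    return err.values[..., np.newaxis] * (lab_orig.pixels - lab_sim.pixels)


def lab_difference_to_rgb(
    diff: np.ndarray, space: ColorSpaceDef = SRGB_D65
) -> np.ndarray:
    """Push a signed L*a*b*-domain difference through the inverse chain
    into linear RGB.

    The two-branch f-inverse and the XYZ→RGB matrix are applied without
    any gamut clipping or companding: only magnitudes of the result are
    consumed downstream, so clipping would discard signal.
    """
    lab = np.asarray(diff, dtype=np.float64)
    L, a, b = lab[..., 0], lab[..., 1], lab[..., 2]
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0
    f = np.stack([fx, fy, fz], axis=-1)
    ratios = _lab_f_inverse(f, CIE_CONSTANTS)
    xyz = ratios * np.asarray(space.white_point)
    return xyz @ build_rgb_to_xyz_matrix(space).inverse.T


def collapse_to_map(
    diff_rgb: np.ndarray,
    cv: CorrectionVector = CorrectionVector(),
    *,
    degenerate_eps: float = 0.0,
) -> np.ndarray:
    """Weighted mean of per-channel magnitudes, min–max normalized.

    ``m(p) = mean_c(w_c * |d_c(p)|)``.  If the pre-normalization peak is
    at or below ``degenerate_eps`` the map is all zeros (degeneracy guard).
    """
    d = np.asarray(diff_rgb, dtype=np.float64)
    if d.ndim != 3 or d.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 difference raster, got {d.shape}")
    m = np.mean(cv.as_array * np.abs(d), axis=-1)
    peak = float(m.max()) if m.size else 0.0
    if peak <= max(degenerate_eps, 0.0):
        return np.zeros_like(m)
    lo = float(m.min())
    if peak - lo <= 0.0:
        return np.zeros_like(m)
    return (m - lo) / (peak - lo)


def gaussian_kernel_3x3(sigma: float = 0.85) -> np.ndarray:
    """Normalized 3×3 Gaussian kernel (σ = 0.85 ≈ the [1 2 1]/4 binomial)."""
    ax = np.array([-1.0, 0.0, 1.0])
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def smooth_3x3(raster: np.ndarray, sigma: float = 0.85) -> np.ndarray:
    """3×3 Gaussian smoothing with reflect padding; kernel sums to 1."""
    r = np.asarray(raster, dtype=np.float64)
    if r.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got shape {r.shape}")
    return ndimage.convolve(r, gaussian_kernel_3x3(sigma), mode="reflect")


def otsu_mask(raster: np.ndarray, *, nbins: int = 256) -> SegmentationMask:
    """Global Otsu threshold of a single-channel raster.

    The value range is histogrammed into ``nbins`` bins and the split
    maximizing the between-class variance is selected; the threshold is
    the center of the last bin of the lower class, and the mask collects
    pixels strictly above it.  A constant raster has no variance to
    split: an empty mask is returned with a warning.
    """
    r = np.asarray(raster, dtype=np.float64)
    if r.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got shape {r.shape}")
    if not np.all(np.isfinite(r)):
        raise ValueError("raster contains non-finite values")
    lo, hi = float(r.min()), float(r.max())
    if hi - lo <= 0.0:
        warnings.warn("constant map: no variance to split, returning empty mask")
        return SegmentationMask(np.zeros(r.shape, dtype=bool), threshold_used=lo)

    hist, edges = np.histogram(r, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist.astype(np.float64) / hist.sum()
    w0 = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_total = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        between = np.where(
            (w0 > 0.0) & (w1 > 0.0) & (hist > 0),
            (mu_total * w0 - mu) ** 2 / (w0 * w1),
            -np.inf,
        )
    # splits are canonicalized to occupied bins: moving a split across an
    # empty bin does not change the partition, so such splits are skipped
    split = int(np.argmax(between[:-1]))  # split after bin `split`
    threshold = float(centers[split])
    return SegmentationMask(r > threshold, threshold_used=threshold)


def otsu_mask_tiled(
    raster: np.ndarray, tiles: tuple[int, int] = (4, 4), *, nbins: int = 256
) -> SegmentationMask:
    """Windowed Otsu: each tile is thresholded independently.

    Constant tiles contribute empty mask regions.  ``threshold_used`` is
    the area-weighted mean of the per-tile thresholds (informational).
    """
    r = np.asarray(raster, dtype=np.float64)
    if r.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got shape {r.shape}")
    ty, tx = tiles
    mask = np.zeros(r.shape, dtype=bool)
    thresholds = []
    weights = []
    for ys in np.array_split(np.arange(r.shape[0]), ty):
        for xs in np.array_split(np.arange(r.shape[1]), tx):
            tile = r[np.ix_(ys, xs)]
            if tile.size == 0 or tile.max() - tile.min() <= 0.0:
                continue
            sub = otsu_mask(tile, nbins=nbins)
            mask[np.ix_(ys, xs)] = sub.values
            thresholds.append(sub.threshold_used)
            weights.append(tile.size)
    thr = float(np.average(thresholds, weights=weights)) if thresholds else float(r.min())
    return SegmentationMask(mask, threshold_used=thr)


def recolor_mask(lab: LabImage, mask: SegmentationMask) -> LabImage:
    """Negate a* and b* inside the mask; L* and unmasked pixels untouched.

    The chroma-plane 180° rotation is an involution: applying it twice
    with the same mask restores the input exactly.
    """
    if mask.values.shape != lab.pixels.shape[:2]:
        raise ValueError(
            f"mask shape {mask.values.shape} does not match image "
            f"{lab.pixels.shape[:2]}"
        )
    out = lab.pixels.copy()
    out[mask.values, 1] = -out[mask.values, 1]
    out[mask.values, 2] = -out[mask.values, 2]
    return LabImage(out)


def _remove_small_components(mask: np.ndarray, min_area: int) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(mask, dtype=np.int64), labels, range(1, n + 1))
    keep = np.flatnonzero(sizes >= min_area) + 1
    return np.isin(labels, keep)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def enhance_image(
    img: EncodedImage,
    deficiency: DeficiencyType | str,
    config: EnhanceConfig = EnhanceConfig(),
    space: ColorSpaceDef = SRGB_D65,
    *,
    debug: bool = False,
) -> EnhancedResult:
    """Run the full saliency-guided recoloring chain on *img*.

    Returns the enhanced image, the segmentation mask, the saliency-error
    map and (optionally) the enhanced image re-rendered through the same
    dichromacy simulation.  With ``debug=True`` all intermediate rasters
    are attached to ``result.debug``.
    """
    deficiency = DeficiencyType.coerce(deficiency)

    sim = simulate_dichromacy(img, deficiency)
    s_orig = lab_saliency(img, space, config=config.saliency)
    s_sim = lab_saliency(sim, space, config=config.saliency)
    err = saliency_error(s_orig, s_sim)

    lab_orig = rgb_to_lab(img, space)
    lab_sim = rgb_to_lab(sim, space)
    diff_lab = weighted_difference(lab_orig, lab_sim, err)
    diff_rgb = lab_difference_to_rgb(diff_lab, space)
    collapsed = collapse_to_map(
        diff_rgb, config.correction, degenerate_eps=config.degenerate_eps
    )
    smoothed = smooth_3x3(collapsed, config.gaussian_sigma)

    if smoothed.max() - smoothed.min() <= 0.0:
        mask = SegmentationMask(
            np.zeros(smoothed.shape, dtype=bool), threshold_used=float(smoothed.max())
        )
    elif config.otsu_mode == "tiled":
        mask = otsu_mask_tiled(smoothed, config.otsu_tiles)
    else:
        mask = otsu_mask(smoothed)
    if config.min_component_frac > 0.0 and mask.area:
        min_area = int(np.ceil(config.min_component_frac * mask.values.size))
        mask = SegmentationMask(
            _remove_small_components(mask.values, min_area), mask.threshold_used
        )

    recolored = recolor_mask(lab_orig, mask)
    clip_count: list[int] = []
    enhanced = lab_to_rgb(recolored, space, clip_count=clip_count)

    simulated_view = (
        simulate_dichromacy(enhanced, deficiency)
        if config.render_simulated_view
        else None
    )
    dbg: dict = {}
    if debug:
        dbg = {
            "saliency_original": s_orig,
            "saliency_simulated": s_sim,
            "weighted_diff_lab": diff_lab,
            "weighted_diff_rgb": diff_rgb,
            "collapsed_map": collapsed,
            "smoothed_map": smoothed,
            "clipped_pixels": clip_count[0] if clip_count else 0,
        }
    return EnhancedResult(
        enhanced=enhanced,
        mask=mask,
        error_map=err,
        simulated_view=simulated_view,
        debug=dbg,
    )
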