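"""Deterministic synthetic stimuli for exercising the pipeline.

Two generators:

* :func:`make_plate` — pseudo-isochromatic dot plates: a field of
  non-overlapping colored dots where dots inside a symbol mask draw from
  a foreground palette and the rest from a background palette.  With a
  red foreground on a green background the symbol is conspicuous to
  trichromats and nearly invisible after dichromat simulation.
* :func:`make_redgreen_scene` — textured red shapes on a textured green
  ground, the standard end-to-end enhancement fixture.

Everything is seeded: the same spec and seed reproduce the image
bit-for-bit, and all emitted colors are in-gamut sRGB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from cvdenhance.colorspace import EncodedImage, LinearImage, decode_gamma, encode_gamma

__all__ = [
    "PlateSpec",
    "make_plate",
    "make_redgreen_scene",
    "make_scene_with_mask",
    "make_symbol_mask",
    "RED_PALETTE",
    "GREEN_PALETTE",
]

#: Reddish / greenish dot palettes (encoded sRGB in [0, 1]).
RED_PALETTE = (
    (0.80, 0.22, 0.16),
    (0.86, 0.34, 0.20),
    (0.72, 0.18, 0.22),
    (0.90, 0.42, 0.30),
)
GREEN_PALETTE = (
    (0.30, 0.60, 0.22),
    (0.42, 0.66, 0.28),
    (0.24, 0.52, 0.26),
    (0.52, 0.70, 0.34),
)


@dataclass(frozen=True)
class PlateSpec:
    """Recipe for a pseudo-isochromatic dot plate."""

    symbol_mask: np.ndarray
    fg_palette: tuple = RED_PALETTE
    bg_palette: tuple = GREEN_PALETTE
    dot_radius_range: tuple[float, float] = (3.0, 6.0)
    coverage: float = 0.35
    seed: int = 0
    paper_color: tuple[float, float, float] = (0.93, 0.91, 0.84)

    def __post_init__(self) -> None:
        if not self.fg_palette or not self.bg_palette:
            raise ValueError("palettes must be nonempty")
        if not (0.0 < self.coverage < 1.0):
            raise ValueError(f"coverage must be in (0, 1), got {self.coverage}")
        r0, r1 = self.dot_radius_range
        if not (0.0 < r0 <= r1):
            raise ValueError(f"invalid dot radius range {self.dot_radius_range}")
        m = np.asarray(self.symbol_mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("symbol_mask must be 2-D")
        object.__setattr__(self, "symbol_mask", m)


def make_symbol_mask(
    size: tuple[int, int], kind: str = "disc", scale: float = 0.30
) -> np.ndarray:
    """Simple symbol shapes (disc, ring, bar) centered in the raster."""
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = scale * min(h, w)
    d = np.hypot(yy - cy, xx - cx)
    if kind == "disc":
        return d <= r
    if kind == "ring":
        return (d <= r) & (d >= 0.55 * r)
    if kind == "bar":
        return (np.abs(yy - cy) <= 0.25 * r) & (np.abs(xx - cx) <= r)
    raise ValueError(f"unknown symbol kind {kind!r}")


def _pack_dots(
    rng: np.random.Generator,
    size: tuple[int, int],
    radius_range: tuple[float, float],
    coverage: float,
    gap: float = 1.0,
    max_attempts_factor: int = 400,
) -> list[tuple[float, float, float]]:
    """Seeded dart-throwing layout of non-overlapping dots.

    Raises when the requested coverage is infeasible for the radius range
    (random non-overlapping packing saturates well below ~0.5).
    """
    h, w = size
    r0, r1 = radius_range
    target = coverage * h * w
    expected = max(1, int(np.ceil(target / (np.pi * r0**2))))
    max_attempts = max_attempts_factor * expected
    dots: list[tuple[float, float, float]] = []
    centers = np.empty((0, 2))
    radii = np.empty(0)
    area = 0.0
    attempts = 0
    while area < target:
        if attempts >= max_attempts:
            raise ValueError(
                f"cannot reach coverage {coverage} with radii {radius_range} "
                f"on a {h}x{w} raster (placed {len(dots)} dots, "
                f"area fraction {area / (h * w):.3f})"
            )
        attempts += 1
        r = rng.uniform(r0, r1)
        cy = rng.uniform(r, h - r)
        cx = rng.uniform(r, w - r)
        if len(dots):
            dist = np.hypot(centers[:, 0] - cy, centers[:, 1] - cx)
            if np.any(dist < radii + r + gap):
                continue
        dots.append((cy, cx, r))
        centers = np.vstack([centers, [cy, cx]])
        radii = np.append(radii, r)
        area += np.pi * r**2
    return dots


def make_plate(
    spec: PlateSpec,
    size: tuple[int, int] | None = None,
    *,
    return_dots: bool = False,
):
    """Render a dot plate; deterministic per ``spec.seed``.

    With ``return_dots=True`` also returns the per-dot records
    ``(cy, cx, r, inside_symbol, palette_index)`` — the natural unit for
    statistical checks on the layout.
    """
    mask = spec.symbol_mask
    if size is None:
        size = mask.shape
    if tuple(size) != mask.shape:
        raise ValueError(
            f"size {size} does not match symbol_mask shape {mask.shape}"
        )
    h, w = size
    rng = np.random.default_rng(spec.seed)
    dots = _pack_dots(rng, (h, w), spec.dot_radius_range, spec.coverage)

    img = np.empty((h, w, 3))
    img[:] = spec.paper_color
    yy, xx = np.mgrid[0:h, 0:w]
    records = []
    for cy, cx, r in dots:
        inside = bool(mask[int(round(cy)), int(round(cx))])
        palette = spec.fg_palette if inside else spec.bg_palette
        idx = int(rng.integers(len(palette)))
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        img[disc] = palette[idx]
        records.append((cy, cx, r, inside, idx))
    image = EncodedImage(np.clip(img, 0.0, 1.0))
    return (image, records) if return_dots else image


# ---------------------------------------------------------------------------
# Red–green scenes
# ---------------------------------------------------------------------------

_GREEN_BG = np.array([0.42, 0.50, 0.38])  # desaturated sage ground


def _speckle(rng: np.random.Generator, shape, amplitude: float, blur: float) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, shape)
    noise = ndimage.gaussian_filter(noise, blur, mode="reflect")
    peak = np.abs(noise).max()
    return amplitude * noise / peak if peak > 0 else noise


def _confusion_partner(
    bg_encoded: np.ndarray, r_linear: float, deficiency: str = "protan"
) -> np.ndarray:
    """Linear-RGB color on the dichromat confusion line through *bg_encoded*.

    Solves for (G, B) so the two surviving cone responses match the
    background's at the requested linear R: the returned color is
    (nearly) indistinguishable from the background after simulation while
    being a saturated red to a trichromat.
    """
    from cvdenhance.cvd_sim import RGB_TO_LMS, DeficiencyType

    keep = (1, 2) if DeficiencyType.coerce(deficiency) is DeficiencyType.PROTAN else (0, 2)
    rows = RGB_TO_LMS[list(keep)]
    bg_lin = decode_gamma(EncodedImage(bg_encoded.reshape(1, 1, 3))).pixels.ravel()
    target = rows @ bg_lin
    gb = np.linalg.solve(rows[:, 1:], target - rows[:, 0] * r_linear)
    return np.array([r_linear, gb[0], gb[1]])


def _encode(linear: np.ndarray) -> np.ndarray:
    return encode_gamma(LinearImage(np.clip(linear, 0.0, 1.0).reshape(1, 1, 3))).pixels.ravel()


def make_scene_with_mask(
    size: tuple[int, int] = (128, 128),
    seed: int = 0,
    *,
    deficiency: str = "protan",
    disc_radius_frac: float = 0.14,
    grayscale: bool = False,
) -> tuple[EncodedImage, np.ndarray]:
    """The standard end-to-end fixture, plus the red disc's pixel mask.

    The scene has two salient objects on a mildly textured sage-green
    ground: a chroma-textured red disc whose colors all sit on the chosen
    dichromat's confusion line through the ground color (so the disc all
    but vanishes after simulation), and a high-contrast luminance blob
    cluster that stays salient in both views.  The saliency difference
    therefore concentrates on the disc, which the enhancement pipeline is
    expected to segment and recolor.

    ``grayscale=True`` replaces every pixel by its luma, giving a
    chroma-free variant with identical geometry (on which the pipeline
    degenerates to the identity).
    """
    h, w = size
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    cy = h * rng.uniform(0.35, 0.65)
    cx = w * rng.uniform(0.22, 0.38)
    radius = disc_radius_frac * min(h, w)
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2

    bg_lin = decode_gamma(EncodedImage(_GREEN_BG.reshape(1, 1, 3))).pixels.ravel()
    red_lin = _confusion_partner(_GREEN_BG, 0.75, deficiency)

    img = np.empty((h, w, 3))
    img[:] = _GREEN_BG
    img += _speckle(rng, (h, w), 0.012, 2.0)[..., np.newaxis]
    img[disc] = _encode(red_lin)
    # chroma dots: linear mixes of ground and red stay on the confusion
    # line, so the whole texture is invisible to the simulated dichromat
    n_dots = max(8, int(1.2 * radius**2))
    for _ in range(n_dots):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        rad = radius * np.sqrt(rng.uniform(0.0, 1.0))
        dy, dx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        dr = rng.uniform(1.5, 2.5)
        t = rng.uniform(0.2, 0.7)
        blob = ((yy - dy) ** 2 + (xx - dx) ** 2 <= dr**2) & disc
        img[blob] = _encode(t * bg_lin + (1.0 - t) * red_lin)
    # luminance distractor: coarse dark/light blobs, salient in both views
    dcy = h * rng.uniform(0.35, 0.65)
    dcx = w * rng.uniform(0.68, 0.82)
    drad = 0.12 * min(h, w)
    for _ in range(14):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        rad = drad * np.sqrt(rng.uniform(0.0, 1.0))
        dy, dx = dcy + rad * np.sin(ang), dcx + rad * np.cos(ang)
        dr = rng.uniform(3.0, 5.0)
        blob = (yy - dy) ** 2 + (xx - dx) ** 2 <= dr**2
        img[blob] = rng.choice([0.10, 0.90])

    img = np.clip(img, 0.0, 1.0)
    if grayscale:
        luma = img @ np.array([0.2126, 0.7152, 0.0722])
        img = np.repeat(luma[..., np.newaxis], 3, axis=-1)
    return EncodedImage(img), disc


def make_redgreen_scene(
    size: tuple[int, int] = (128, 128), seed: int = 0, *, grayscale: bool = False
) -> EncodedImage:
    """Standard end-to-end enhancement fixture (see
    :func:`make_scene_with_mask` for the variant exposing the disc mask)."""
    img, _ = make_scene_with_mask(size, seed, grayscale=grayscale)
    return img
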