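"""Conversions among encoded RGB, linear RGB, CIE XYZ and CIE L*a*b*.

The conversion chain is

    encoded RGB  <--companding-->  linear RGB  <--3x3 matrix-->  XYZ
                                                  <--f-branches-->  L*a*b*

The RGB→XYZ matrix is built from chromaticity coordinates of the three
primaries and the white point: each primary's tristimulus column is
scaled so that RGB = (1,1,1) maps exactly onto the white point.  The
L*a*b* conversion uses the exact rational CIE junction constants
ε = 216/24389 and k = 24389/27, which make the cube-root and linear
branches meet continuously.

Note on symbols: chromaticity coordinates of the primaries and the
white-relative ratios X/X_W, Y/Y_W, Z/Z_W are distinct quantities even
though both are conventionally written (x_r, y_r, z_r); here the former
live in :class:`ColorSpaceDef` and the latter only inside
:func:`xyz_to_lab` / :func:`lab_to_xyz`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "CIE_CONSTANTS",
    "SRGB_D65",
    "CIEConstants",
    "ColorSpaceDef",
    "ConversionMatrix",
    "EncodedImage",
    "LabImage",
    "LinearImage",
    "XYZImage",
    "build_rgb_to_xyz_matrix",
    "decode_gamma",
    "encode_gamma",
    "lab_to_rgb",
    "lab_to_xyz",
    "linear_to_xyz",
    "rgb_to_lab",
    "xyz_to_lab",
    "xyz_to_linear",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColorSpaceDef:
    """An RGB color space: three primaries (chromaticities) plus white point.

    Parameters
    ----------
    primaries:
        ``((x_r, y_r), (x_g, y_g), (x_b, y_b))`` chromaticity coordinates.
    white_point:
        ``(X_W, Y_W, Z_W)`` tristimulus of the reference white, ``Y_W = 1``.
    name:
        Human-readable label used in error messages and config files.
    """

    primaries: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    white_point: tuple[float, float, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        for i, (x, y) in enumerate(self.primaries):
            if not (x >= 0.0 and y > 0.0 and x + y <= 1.0):
                raise ValueError(
                    f"primary {i} of {self.name!r} has invalid chromaticity "
                    f"({x}, {y}): need x >= 0, y > 0, x + y <= 1"
                )
        if self.white_point[1] != 1.0:
            raise ValueError(
                f"white point of {self.name!r} must have Y_W = 1, got {self.white_point[1]}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ColorSpaceDef":
        prim = tuple(tuple(float(v) for v in p) for p in d["primaries"])
        wp = tuple(float(v) for v in d["white_point"])
        return cls(primaries=prim, white_point=wp, name=str(d.get("name", "custom")))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ColorSpaceDef":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class ConversionMatrix:
    """3x3 matrix mapping linear RGB column vectors to XYZ."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError(f"conversion matrix must be 3x3, got {m.shape}")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass(frozen=True)
class CIEConstants:
    """Junction constants of the L*a*b* two-branch transfer function.

    Stored as exact rationals evaluated in double precision so the two
    branches agree at the junction to machine accuracy.
    """

    epsilon: float = float(Fraction(216, 24389))
    kappa: float = float(Fraction(24389, 27))


CIE_CONSTANTS = CIEConstants()

#: sRGB primaries with the D65 white point; the package-wide default.
SRGB_D65 = ColorSpaceDef(
    primaries=((0.64, 0.33), (0.30, 0.60), (0.15, 0.06)),
    white_point=(0.95047, 1.0, 1.08883),
    name="sRGB/D65",
)


def _as_pixels(pixels: np.ndarray, nchan: int = 3) -> np.ndarray:
    p = np.asarray(pixels, dtype=np.float64)
    if p.ndim != 3 or p.shape[2] != nchan:
        raise ValueError(f"expected H x W x {nchan} raster, got shape {p.shape}")
    return p


@dataclass(frozen=True)
class EncodedImage:
    """Gamma-encoded RGB raster with values in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = _as_pixels(self.pixels)
        if p.size and (p.min() < 0.0 or p.max() > 1.0):
            raise ValueError(
                f"encoded values must lie in [0, 1]; found range "
                f"[{p.min():.6g}, {p.max():.6g}]"
            )
        object.__setattr__(self, "pixels", p)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class LinearImage:
    """Linear-light RGB raster in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", _as_pixels(self.pixels))


@dataclass(frozen=True)
class XYZImage:
    """Tristimulus raster, Y relative to white (Y_W = 1)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", _as_pixels(self.pixels))


@dataclass(frozen=True)
class LabImage:
    """CIE L*a*b* raster: L* in [0, 100], a*/b* signed opponent axes."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = _as_pixels(self.pixels)
        L = p[..., 0]
        if L.size and (L.min() < -1e-9 or L.max() > 100.0 + 1e-9):
            raise ValueError(
                f"L* must lie in [0, 100]; found range [{L.min():.6g}, {L.max():.6g}]"
            )
        object.__setattr__(self, "pixels", p)


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------


def build_rgb_to_xyz_matrix(space: ColorSpaceDef) -> ConversionMatrix:
    """Build the linear-RGB → XYZ matrix of *space*.

    Each primary's unscaled tristimulus column is ``(x/y, 1, (1-x-y)/y)``;
    per-primary scales ``(S_r, S_g, S_b)`` are then solved so the matrix
    maps (1, 1, 1) exactly to the white point.

    Raises
    ------
    ValueError
        If the primaries are collinear (singular column matrix).
    """
    cols = []
    for x, y in space.primaries:
        cols.append((x / y, 1.0, (1.0 - x - y) / y))
    m0 = np.array(cols, dtype=np.float64).T  # columns are (X_i, Y_i, Z_i)
    try:
        s = np.linalg.solve(m0, np.asarray(space.white_point, dtype=np.float64))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"primaries of {space.name!r} are degenerate (collinear chromaticities "
            f"{space.primaries}); cannot build a conversion matrix"
        ) from exc
    return ConversionMatrix(m0 * s[np.newaxis, :])


# ---------------------------------------------------------------------------
# Companding
# ---------------------------------------------------------------------------

_SRGB_LINEAR_KNEE = 0.04045  # encoded-side junction of the IEC 61966-2-1 curve


def decode_gamma(img: EncodedImage) -> LinearImage:
    """IEC sRGB electro-optical decoding, elementwise."""
    v = img.pixels
    lo = v <= _SRGB_LINEAR_KNEE
    # (1000 v + 55) / 1055 rather than (v + 0.055) / 1.055: exact at v = 1
    out = np.where(lo, v / 12.92, ((1000.0 * v + 55.0) / 1055.0) ** 2.4)
    return LinearImage(out)


def encode_gamma(img: LinearImage, *, clip_count: list | None = None) -> EncodedImage:
    """Inverse of :func:`decode_gamma`; out-of-[0,1] inputs are clipped first.

    If ``clip_count`` is a list, the number of clipped samples is appended
    to it (the companding itself never fails).
    """
    v = img.pixels
    n_clipped = int(np.count_nonzero((v < 0.0) | (v > 1.0)))
    if clip_count is not None:
        clip_count.append(n_clipped)
    v = np.clip(v, 0.0, 1.0)
    lo = v <= _SRGB_LINEAR_KNEE / 12.92
    out = np.where(lo, v * 12.92, (1055.0 * v ** (1.0 / 2.4) - 55.0) / 1000.0)
    return EncodedImage(np.clip(out, 0.0, 1.0))


# ---------------------------------------------------------------------------
# XYZ <-> Lab
# ---------------------------------------------------------------------------


def linear_to_xyz(img: LinearImage, space: ColorSpaceDef = SRGB_D65) -> XYZImage:
    m = build_rgb_to_xyz_matrix(space).matrix
    return XYZImage(img.pixels @ m.T)


def xyz_to_linear(img: XYZImage, space: ColorSpaceDef = SRGB_D65) -> LinearImage:
    m_inv = build_rgb_to_xyz_matrix(space).inverse
    return LinearImage(img.pixels @ m_inv.T)


def _lab_f(ratio: np.ndarray, consts: CIEConstants) -> np.ndarray:
    # cube root above the junction, affine below; continuous at ratio == ε
    return np.where(
        ratio > consts.epsilon,
        np.cbrt(ratio),
        (consts.kappa * ratio + 16.0) / 116.0,
    )


def _lab_f_inverse(f: np.ndarray, consts: CIEConstants) -> np.ndarray:
    f3 = f**3
    return np.where(f3 > consts.epsilon, f3, (116.0 * f - 16.0) / consts.kappa)


def xyz_to_lab(
    img: XYZImage,
    space: ColorSpaceDef = SRGB_D65,
    consts: CIEConstants = CIE_CONSTANTS,
) -> LabImage:
    """Convert XYZ to L*a*b* relative to the white point of *space*.

    Per pixel: white-relative ratios are pushed through the two-branch
    f-function, then ``L* = 116 f_y - 16``, ``a* = 500 (f_x - f_y)``,
    ``b* = 200 (f_y - f_z)``.

    Raises
    ------
    ValueError
        If any tristimulus value is negative.
    """
    xyz = img.pixels
    if xyz.size and xyz.min() < 0.0:
        raise ValueError(f"negative tristimulus values (min {xyz.min():.6g})")
    wp = np.asarray(space.white_point, dtype=np.float64)
    f = _lab_f(xyz / wp, consts)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    lab = np.stack(
        [116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1
    )
    return LabImage(lab)


def lab_to_xyz(
    img: LabImage,
    space: ColorSpaceDef = SRGB_D65,
    consts: CIEConstants = CIE_CONSTANTS,
) -> XYZImage:
    """Exact algebraic inverse of :func:`xyz_to_lab` (both branches)."""
    lab = img.pixels
    L, a, b = lab[..., 0], lab[..., 1], lab[..., 2]
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0
    f = np.stack([fx, fy, fz], axis=-1)
    ratios = _lab_f_inverse(f, consts)
    wp = np.asarray(space.white_point, dtype=np.float64)
    return XYZImage(ratios * wp)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


def rgb_to_lab(img: EncodedImage, space: ColorSpaceDef = SRGB_D65) -> LabImage:
    """Encoded RGB → L*a*b* (companding, matrix, f-branches)."""
    return xyz_to_lab(linear_to_xyz(decode_gamma(img), space), space)


def lab_to_rgb(
    img: LabImage,
    space: ColorSpaceDef = SRGB_D65,
    *,
    clip_count: list | None = None,
) -> EncodedImage:
    """L*a*b* → encoded RGB; out-of-gamut values are clipped in linear RGB."""
    linear = xyz_to_linear(lab_to_xyz(img, space), space)
    return encode_gamma(linear, clip_count=clip_count)


def lab_channels(lab: LabImage) -> Sequence[np.ndarray]:
    """The (L*, a*, b*) planes of *lab* as separate 2-D arrays."""
    return lab.pixels[..., 0], lab.pixels[..., 1], lab.pixels[..., 2]
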