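"""Dichromatic (protan/deutan) perception simulation.

Implements the Viénot–Brettel–Mollon (1999) linear-RGB reduction: linear
RGB is mapped into an LMS cone space with a Smith–Pokorny-style
transform, the missing cone's signal is replaced by a linear combination
of the two remaining ones (a projection onto the plane through the
achromatic axis and a preserved blue–yellow hue axis), and the result is
mapped back to linear RGB.  The projection is idempotent, and the
achromatic axis is (numerically) a fixed point of the whole chain.

Tritanopia is intentionally unsupported: the pipeline targets red–green
chromatic contrast only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from cvdenhance.colorspace import EncodedImage, LinearImage, decode_gamma, encode_gamma

__all__ = [
    "DeficiencyType",
    "DichromatModel",
    "build_dichromat_model",
    "simulate_dichromacy",
]


class DeficiencyType(enum.Enum):
    """Supported dichromacies (closed enumeration)."""

    PROTAN = "protan"
    DEUTAN = "deutan"

    @classmethod
    def coerce(cls, value: "DeficiencyType | str") -> "DeficiencyType":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"unsupported deficiency {value!r}: choose 'protan' or 'deutan' "
                "(tritan is out of scope: the pipeline addresses red-green "
                "contrast only)"
            ) from None


# Viénot, Brettel & Mollon (1999) constants: linear RGB -> LMS and back.
RGB_TO_LMS = np.array(
    [
        [17.8824, 43.5161, 4.11935],
        [3.45565, 27.1554, 3.86714],
        [0.0299566, 0.184309, 1.46709],
    ]
)

LMS_TO_RGB = np.array(
    [
        [0.0809444479, -0.130504409, 0.116721066],
        [-0.0102485335, 0.0540193266, -0.113614708],
        [-0.000365296938, -0.00412161469, 0.693511405],
    ]
)

# Rank-2 reductions replacing the missing cone's row.
_PROJECTIONS = {
    DeficiencyType.PROTAN: np.array(
        [
            [0.0, 2.02344, -2.52581],
            [0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
        ]
    ),
    DeficiencyType.DEUTAN: np.array(
        [
            [1.0, 0.0, 0.0],
            [0.494207, 0.0, 1.24827],
            [0.0, 0.0, 1.0],
        ]
    ),
}


@dataclass(frozen=True)
class DichromatModel:
    """Linear reduction ``lms_to_rgb @ projection @ rgb_to_lms``."""

    deficiency: DeficiencyType
    rgb_to_lms: np.ndarray
    projection: np.ndarray
    lms_to_rgb: np.ndarray

    @property
    def full_matrix(self) -> np.ndarray:
        """The composed 3x3 linear-RGB → linear-RGB reduction."""
        return self.lms_to_rgb @ self.projection @ self.rgb_to_lms

    def apply_linear(self, img: LinearImage) -> LinearImage:
        return LinearImage(img.pixels @ self.full_matrix.T)


def build_dichromat_model(deficiency: DeficiencyType | str) -> DichromatModel:
    """Return the linear-RGB dichromat reduction for *deficiency*."""
    deficiency = DeficiencyType.coerce(deficiency)
    return DichromatModel(
        deficiency=deficiency,
        rgb_to_lms=RGB_TO_LMS.copy(),
        projection=_PROJECTIONS[deficiency].copy(),
        lms_to_rgb=LMS_TO_RGB.copy(),
    )


def simulate_dichromacy(
    img: EncodedImage, deficiency: DeficiencyType | str
) -> EncodedImage:
    """Render *img* as perceived by the chosen dichromat.

    Decode to linear RGB, apply the model's linear chain, clip to the
    display gamut and re-encode.  Deterministic; output shape equals the
    input shape.
    """
    model = build_dichromat_model(deficiency)
    reduced = model.apply_linear(decode_gamma(img))
    return encode_gamma(LinearImage(np.clip(reduced.pixels, 0.0, 1.0)))
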