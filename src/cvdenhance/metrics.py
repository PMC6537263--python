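"""NSS and AUC agreement between a saliency/fixation map and fixation points.

NSS z-scores the map with the *population* standard deviation and
averages the z-values at the fixation pixels (repeated fixations count;
0 ≈ chance).  AUC is the Judd-style rank statistic: the probability that
a fixated pixel outranks a non-fixated one, ties counted one half —
identical to the trapezoidal ROC area over all thresholds.  Fixation
pixels are deduplicated for AUC positives; all remaining pixels are
negatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["FixationPointSet", "auc", "nss"]


@dataclass(frozen=True)
class FixationPointSet:
    """Pixel locations of observed fixations (x, y), 0-based."""

    points: tuple[tuple[int, int], ...]
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "points", tuple((int(x), int(y)) for x, y in self.points)
        )

    def __len__(self) -> int:
        return len(self.points)

    def validate_on(self, shape: tuple[int, int]) -> None:
        h, w = shape
        for x, y in self.points:
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(
                    f"fixation ({x}, {y}) is off a {w}x{h} map"
                )


def _as_map(values) -> np.ndarray:
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 2:
        raise ValueError(f"expected a 2-D map, got shape {v.shape}")
    return v


def nss(map_values, fixations: FixationPointSet) -> float:
    """Mean z-scored map value at the fixation pixels."""
    v = _as_map(map_values)
    if len(fixations) == 0:
        raise ValueError("cannot compute NSS with no fixations")
    fixations.validate_on(v.shape)
    std = v.std()  # population standard deviation
    if std == 0.0:
        raise ValueError("cannot compute NSS of a zero-variance map")
    z = (v - v.mean()) / std
    return float(np.mean([z[y, x] for x, y in fixations.points]))


def auc(map_values, fixations: FixationPointSet) -> float:
    """Probability a fixated pixel outranks a non-fixated one (ties ½)."""
    v = _as_map(map_values)
    if len(fixations) == 0:
        raise ValueError("cannot compute AUC with no fixations")
    fixations.validate_on(v.shape)
    pos_mask = np.zeros(v.shape, dtype=bool)
    for x, y in fixations.points:
        pos_mask[y, x] = True
    n_pos = int(pos_mask.sum())
    n_neg = v.size - n_pos
    if n_neg == 0:
        raise ValueError("cannot compute AUC: every pixel is fixated")
    ranks = rankdata(v.ravel(), method="average").reshape(v.shape)
    rank_sum = float(ranks[pos_mask].sum())
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)
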