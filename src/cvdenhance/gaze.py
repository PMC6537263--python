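"""Fixation maps from binocular gaze logs, and simulated gaze traces.

A gaze log is a time-ordered sequence of binocular samples.  Each sample
is reduced to a single fixation point by averaging the available eyes;
points are rounded to the nearest pixel and accumulated into an integer
count raster which is then blurred with a mass-preserving Gaussian.
Early samples (default: the first 200 ms, when gaze is center-biased)
can be excluded.

The CSV dialect is ``t_ms,lx,ly,rx,ry,valid`` with empty fields for
missing coordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "FixationMap",
    "GazeSample",
    "GazeTrace",
    "binocular_point",
    "build_fixation_map",
    "default_sigma_px",
    "read_gaze_csv",
    "simulate_gaze",
    "write_gaze_csv",
]


@dataclass(frozen=True)
class GazeSample:
    """One binocular tracker sample; either eye may be missing."""

    t: float  # milliseconds from stimulus onset
    left: tuple[float, float] | None
    right: tuple[float, float] | None
    valid: bool = True

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"timestamp must be >= 0, got {self.t}")
        for eye in (self.left, self.right):
            if eye is not None and not all(math.isfinite(c) for c in eye):
                raise ValueError(f"non-finite eye coordinates: {eye}")


@dataclass(frozen=True)
class GazeTrace:
    samples: tuple[GazeSample, ...]
    screen: tuple[int, int]  # (width, height) pixels
    duration_ms: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        w, h = self.screen
        if w <= 0 or h <= 0:
            raise ValueError(f"screen dimensions must be positive, got {self.screen}")
        ts = [s.t for s in self.samples]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("sample timestamps must be nondecreasing")


@dataclass(frozen=True)
class FixationMap:
    """Accumulated gaze counts and their mass-preserving Gaussian blur."""

    counts: np.ndarray  # H x W integer accumulator
    smoothed: np.ndarray  # H x W, sums to counts.sum()
    sigma_px: float


def binocular_point(s: GazeSample) -> tuple[float, float] | None:
    """Mean of the available eyes; one-eyed samples pass through; both
    missing → ``None``."""
    if s.left is not None and s.right is not None:
        return (
            0.5 * (s.left[0] + s.right[0]),
            0.5 * (s.left[1] + s.right[1]),
        )
    return s.left if s.left is not None else s.right


def default_sigma_px(
    *,
    degrees: float = 1.0,
    distance_cm: float = 70.0,
    screen_diag_in: float = 22.0,
    screen_px: tuple[int, int] = (1920, 1080),
) -> float:
    """Smoothing scale in pixels subtending *degrees* of visual angle.

    Defaults model the acquisition geometry: a 22-inch 1920×1080 monitor
    viewed from 70 cm, where 1° ≈ 48 px.
    """
    w_px, h_px = screen_px
    aspect = w_px / h_px
    diag_cm = screen_diag_in * 2.54
    width_cm = diag_cm * aspect / math.hypot(aspect, 1.0)
    px_per_cm = w_px / width_cm
    extent_cm = 2.0 * distance_cm * math.tan(math.radians(degrees) / 2.0)
    return extent_cm * px_per_cm


def _mass_preserving_blur(counts: np.ndarray, sigma_px: float) -> np.ndarray:
    # Per-source kernel renormalization at borders: each count's (truncated,
    # normalized) kernel is rescaled by the in-image kernel mass at its own
    # location, so the blurred raster sums exactly to counts.sum().
    if sigma_px <= 0.0:
        return counts.astype(np.float64)
    weight = ndimage.gaussian_filter(
        np.ones_like(counts, dtype=np.float64), sigma_px, mode="constant"
    )
    return ndimage.gaussian_filter(counts / weight, sigma_px, mode="constant")


def build_fixation_map(
    trace: GazeTrace,
    exclude_initial_ms: float = 200.0,
    sigma_px: float | None = None,
) -> FixationMap:
    """Accumulate retained on-screen gaze points into a smoothed map.

    Samples with ``t < exclude_initial_ms``, invalid samples, samples with
    both eyes missing, and points off-screen after rounding to the nearest
    pixel are dropped; the rest increment per-pixel counts.
    """
    if exclude_initial_ms < 0:
        raise ValueError(f"exclude_initial_ms must be >= 0, got {exclude_initial_ms}")
    if sigma_px is None:
        sigma_px = default_sigma_px()
    w, h = trace.screen
    counts = np.zeros((h, w), dtype=np.int64)
    for s in trace.samples:
        if s.t < exclude_initial_ms or not s.valid:
            continue
        pt = binocular_point(s)
        if pt is None:
            continue
        # round half to even, matching numpy convention
        x = int(np.round(pt[0]))
        y = int(np.round(pt[1]))
        if 0 <= x < w and 0 <= y < h:
            counts[y, x] += 1
    if counts.sum() == 0:
        warnings.warn("no retained gaze samples: fixation map is all zeros")
        return FixationMap(counts, counts.astype(np.float64), sigma_px)
    return FixationMap(counts, _mass_preserving_blur(counts, sigma_px), sigma_px)


def simulate_gaze(
    hotspots: Sequence[tuple[float, float, float]],
    screen: tuple[int, int],
    duration_ms: float = 3000.0,
    rate_hz: float = 55.0,
    noise_px: float = 5.0,
    center_bias_ms: float = 200.0,
    seed: int = 0,
) -> GazeTrace:
    """Seeded synthetic binocular trace over a weighted hotspot mixture.

    Samples are taken at ``t_i = i / rate_hz`` for the whole duration
    (3000 ms at 55 Hz gives 165 samples).  Samples before
    ``center_bias_ms`` are jittered around the screen center; later ones
    are drawn from the hotspot mixture with isotropic Gaussian jitter of
    ``noise_px``.  Each eye gets independent jitter of one pixel around
    the fixation point.
    """
    if rate_hz <= 0:
        raise ValueError(f"rate_hz must be positive, got {rate_hz}")
    if duration_ms <= 0:
        raise ValueError(f"duration_ms must be positive, got {duration_ms}")
    hotspots = list(hotspots)
    weights = np.array([wgt for _, _, wgt in hotspots], dtype=np.float64)
    if len(hotspots) == 0 or weights.min() < 0 or weights.sum() <= 0:
        raise ValueError("hotspot weights must be >= 0 and sum > 0")
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    w, h = screen
    n = int(math.floor(duration_ms * rate_hz / 1000.0))
    period = 1000.0 / rate_hz
    centers = np.array([(x, y) for x, y, _ in hotspots])
    samples = []
    for i in range(n):
        t = i * period
        if t < center_bias_ms:
            base = np.array([w / 2.0, h / 2.0])
        else:
            base = centers[rng.choice(len(hotspots), p=weights)]
        point = base + rng.normal(0.0, noise_px, size=2)
        left = tuple(point + rng.normal(0.0, 1.0, size=2))
        right = tuple(point + rng.normal(0.0, 1.0, size=2))
        samples.append(GazeSample(t=t, left=left, right=right, valid=True))
    return GazeTrace(samples=tuple(samples), screen=screen, duration_ms=duration_ms)


# ---------------------------------------------------------------------------
# CSV I/O (dialect: t_ms,lx,ly,rx,ry,valid — empty fields mean missing)
# ---------------------------------------------------------------------------


def read_gaze_csv(
    path: str | Path, screen: tuple[int, int], duration_ms: float | None = None
) -> GazeTrace:
    df = pd.read_csv(path)
    expected = ["t_ms", "lx", "ly", "rx", "ry", "valid"]
    if list(df.columns) != expected:
        raise ValueError(
            f"gaze CSV {path} must have columns {expected}, got {list(df.columns)}"
        )
    samples = []
    for row in df.itertuples(index=False):
        left = None if pd.isna(row.lx) or pd.isna(row.ly) else (float(row.lx), float(row.ly))
        right = None if pd.isna(row.rx) or pd.isna(row.ry) else (float(row.rx), float(row.ry))
        samples.append(
            GazeSample(
                t=float(row.t_ms), left=left, right=right, valid=bool(row.valid)
            )
        )
    if duration_ms is None:
        duration_ms = samples[-1].t if samples else 0.0
    return GazeTrace(samples=tuple(samples), screen=screen, duration_ms=duration_ms)


def write_gaze_csv(trace: GazeTrace, path: str | Path) -> None:
    rows = []
    for s in trace.samples:
        rows.append(
            {
                "t_ms": s.t,
                "lx": s.left[0] if s.left else "",
                "ly": s.left[1] if s.left else "",
                "rx": s.right[0] if s.right else "",
                "ry": s.right[1] if s.right else "",
                "valid": int(s.valid),
            }
        )
    pd.DataFrame(rows, columns=["t_ms", "lx", "ly", "rx", "ry", "valid"]).to_csv(
        path, index=False
    )
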