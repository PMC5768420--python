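"""Lamellipodium-occupancy (LO) morphometrics.

Phalloidin-stained neurons are profiled along a circle of radius 8 µm around
the cell centre; contiguous above-threshold runs of the angular intensity
profile are the lamellipodial arcs.  Each arc's occupancy is its angular span
divided by the full periphery (LO = span / 2π, independent of the radius),
and the cell is called a segmented lamellipodium (SL) when every arc occupies
less than one third of the periphery, or a broad lamellipodium (BL) when the
largest arc (the "major LO") reaches one third or more.

Conventions: images are row-major rasters with the origin at the top-left;
angles are measured counter-clockwise from the +x axis in the right-handed
mathematical frame obtained by flipping y, so the sample at angle theta sits
at pixel ``(col, row) = (cx + r cos(theta), cy - r sin(theta))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "AngularProfile",
    "ArcSegment",
    "LOResult",
    "SL_BL_BOUNDARY",
    "oval_profile",
    "normalize_background",
    "segment_arcs",
    "occupancy",
    "classify",
    "lo_histogram",
    "profile_to_lo",
]

#: Major-LO boundary between the segmented (SL, below) and broad (BL, at or
#: above) lamellipodium phenotypes: one third of the cell periphery.
SL_BL_BOUNDARY = 1.0 / 3.0


@dataclass(frozen=True)
class AngularProfile:
    """Circular intensity samples at uniformly spaced angles.

    ``angles[k] = 2*pi*k/n`` with wraparound (index n-1 is adjacent to 0);
    intensities are non-negative and, after :func:`normalize_background`,
    expressed in units of the background level.
    """

    radius_um: float
    intensities: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size < 36:
            raise ValueError("profile needs >= 36 angular samples")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("intensities must be finite and non-negative")
        if not (self.radius_um > 0):
            raise ValueError("radius_um must be > 0")
        object.__setattr__(self, "intensities", arr)

    @property
    def n(self) -> int:
        return self.intensities.size

    @property
    def angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n) / self.n


@dataclass(frozen=True)
class ArcSegment:
    """One contiguous above-threshold arc on the sampling circle."""

    start_angle: float     # radians in [0, 2*pi)
    span: float            # radians in (0, 2*pi]
    mean_intensity: float

    def __post_init__(self):
        if not (0 < self.span <= 2 * np.pi + 1e-12):
            raise ValueError("arc span must lie in (0, 2*pi]")


@dataclass(frozen=True)
class LOResult:
    """Per-cell occupancy summary: arcs, their LO values, and the major LO."""

    arcs: tuple
    lo_values: tuple

    @property
    def major_lo(self) -> float:
        return max(self.lo_values) if self.lo_values else 0.0


def oval_profile(image: np.ndarray, center: tuple[float, float],
                 radius_um: float, pixel_size_um: float,
                 n: int = 360) -> AngularProfile:
    """Sample a grayscale image along a circle by bilinear interpolation.

    ``center`` is ``(x, y)`` in pixel coordinates (x = column, y = row).
    The circle must lie fully inside the image.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be a 2-D grayscale raster")
    if n < 36:
        raise ValueError("need n >= 36 angular samples")
    cx, cy = float(center[0]), float(center[1])
    r_px = radius_um / pixel_size_um
    h, w = img.shape
    if (cx - r_px < 0 or cx + r_px > w - 1 or cy - r_px < 0 or cy + r_px > h - 1):
        raise ValueError(
            f"sampling circle (centre=({cx},{cy}), r={r_px:.1f} px) exceeds "
            f"image bounds {w}x{h}")
    theta = 2.0 * np.pi * np.arange(n) / n
    cols = cx + r_px * np.cos(theta)
    rows = cy - r_px * np.sin(theta)           # y-flip: ccw from +x axis
    vals = map_coordinates(img, np.vstack([rows, cols]), order=1, mode="nearest")
    return AngularProfile(radius_um=radius_um, intensities=np.maximum(vals, 0.0))


def normalize_background(profile: AngularProfile,
                         background: float) -> AngularProfile:
    """Divide intensities by a scalar background level (> 0)."""
    if not (background > 0):
        raise ValueError("background must be > 0")
    return AngularProfile(radius_um=profile.radius_um,
                          intensities=profile.intensities / background)


def segment_arcs(profile: AngularProfile, threshold: float,
                 min_samples: int = 2) -> list[ArcSegment]:
    """Maximal runs of consecutive samples >= threshold, merged across 0/2π.

    Runs shorter than ``min_samples`` are discarded as single-pixel noise.
    An all-positive profile yields one full-circle arc.
    """
    if not (threshold > 0):
        raise ValueError("threshold must be > 0")
    mask = profile.intensities >= threshold
    n = profile.n
    if not mask.any():
        return []
    dtheta = 2.0 * np.pi / n
    if mask.all():
        return [ArcSegment(start_angle=0.0, span=2.0 * np.pi,
                           mean_intensity=float(profile.intensities.mean()))]
    # rotate so index 0 is below threshold, making runs interior
    first_low = int(np.argmin(mask))
    rolled = np.roll(mask, -first_low)
    vals = np.roll(profile.intensities, -first_low)
    arcs = []
    edges = np.flatnonzero(np.diff(np.concatenate([[False], rolled, [False]]).astype(int)))
    for start, stop in zip(edges[::2], edges[1::2]):
        length = stop - start
        if length < min_samples:
            continue
        orig_start = (start + first_low) % n
        arcs.append(ArcSegment(
            start_angle=orig_start * dtheta,
            span=length * dtheta,
            mean_intensity=float(vals[start:stop].mean())))
    return arcs


def occupancy(arc: ArcSegment, radius_um: float = 8.0) -> float:
    """Lamellipodium occupancy of one arc: arc length over the periphery.

    LO = (span * r) / (2π r) = span / 2π — independent of the radius.
    """
    if not (radius_um > 0):
        raise ValueError("radius_um must be > 0")
    return arc.span / (2.0 * np.pi)


def classify(lo: LOResult) -> str:
    """Phenotype call from the major LO: 'none' without arcs, 'BL' when the
    major LO reaches 1/3 of the periphery, 'SL' otherwise."""
    if not lo.arcs:
        return "none"
    return "BL" if lo.major_lo >= SL_BL_BOUNDARY else "SL"


def lo_histogram(population: Sequence[LOResult],
                 bin_width: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of major-LO values over [0, 1].

    Returns ``(counts, edges)`` with right-open bins except the last, so the
    total count equals the population size.
    """
    if not (0 < bin_width <= 1):
        raise ValueError("bin_width must lie in (0, 1]")
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.minimum(bin_width * np.arange(n_bins + 1), 1.0)
    values = [lo.major_lo for lo in population]
    counts, _ = np.histogram(values, bins=edges)
    return counts, edges


def profile_to_lo(profile: AngularProfile, threshold: float = 2.0,
                  background: float | None = None,
                  min_samples: int = 2) -> LOResult:
    """Convenience pipeline: optional normalization, arc segmentation, LO.

    ``threshold`` is in units of the (normalized) background; pass
    ``background`` to normalize a raw profile first.
    """
    if background is not None:
        profile = normalize_background(profile, background)
    arcs = segment_arcs(profile, threshold, min_samples=min_samples)
    return LOResult(arcs=tuple(arcs),
                    lo_values=tuple(occupancy(a, profile.radius_um) for a in arcs))
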