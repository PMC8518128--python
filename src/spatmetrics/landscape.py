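"""Rectangular landscapes, point patterns and the unit-intensity rescaling.

All of the framework equations implemented in :mod:`spatmetrics.theory` and
:mod:`spatmetrics.negbin` are written in units of length scaled so that the
first-order intensity is one point per unit area.  In these units a plot of
area ``A`` has expected abundance ``mu(A) = A``, which makes every metric a
function of geometry alone.  This module owns that convention: patterns are
stored in whatever units the data come in, and :func:`rescale_to_unit_intensity`
moves them into scaled units, returning the scale factor so downstream code
can convert back at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Landscape",
    "PointPattern",
    "rescale_to_unit_intensity",
    "unscale_coords",
]


@dataclass(frozen=True)
class Landscape:
    """An axis-aligned rectangular observation window with origin (0, 0)."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"landscape dimensions must be positive, got {self.width} x {self.height}"
            )

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def min_side(self) -> float:
        return min(self.width, self.height)


@dataclass
class PointPattern:
    """A set of 2D points inside a rectangular landscape.

    The pattern is assumed orderly (no two points at the same location),
    homogeneous and isotropic; duplicate coordinates are rejected unless
    ``jitter`` is supplied, in which case duplicates are displaced by a
    uniform perturbation of that magnitude (clipped to the window).
    """

    coords: np.ndarray
    landscape: Landscape
    jitter: float | None = None
    rng: np.random.Generator | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.size == 0:
            coords = coords.reshape(0, 2)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array of x, y positions")
        w, h = self.landscape.width, self.landscape.height
        inside = (
            (coords[:, 0] >= 0)
            & (coords[:, 0] <= w)
            & (coords[:, 1] >= 0)
            & (coords[:, 1] <= h)
        )
        if not inside.all():
            bad = np.flatnonzero(~inside)
            raise ValueError(
                f"{bad.size} point(s) outside the {w} x {h} window (rows {bad[:10].tolist()})"
            )
        dup = _duplicate_rows(coords)
        if dup.size:
            if self.jitter is None:
                raise ValueError(
                    "duplicate coordinates at rows "
                    f"{dup[:10].tolist()}; orderly patterns forbid coincident points "
                    "(pass jitter=eps to displace them)"
                )
            rng = self.rng if self.rng is not None else np.random.default_rng(0)
            coords = coords.copy()
            coords[dup] += rng.uniform(-self.jitter, self.jitter, size=(dup.size, 2))
            coords[:, 0] = np.clip(coords[:, 0], 0.0, w)
            coords[:, 1] = np.clip(coords[:, 1], 0.0, h)
        self.coords = coords

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def intensity(self) -> float:
        """First-order intensity: points per unit area of the window."""
        return self.n / self.landscape.area


def _duplicate_rows(coords: np.ndarray) -> np.ndarray:
    """Indices of rows that repeat an earlier row exactly."""
    if coords.shape[0] < 2:
        return np.empty(0, dtype=int)
    _, first = np.unique(coords, axis=0, return_index=True)
    keep = np.zeros(coords.shape[0], dtype=bool)
    keep[first] = True
    return np.flatnonzero(~keep)


def rescale_to_unit_intensity(pattern: PointPattern) -> tuple[PointPattern, float]:
    """Rescale a pattern so its first-order intensity equals 1.

    Returns ``(scaled_pattern, s)`` where ``new_coord = old_coord / s`` and
    ``s = sqrt(window_area / n)``.  The scaled window has area exactly ``n``,
    hence intensity exactly 1, and the expected count in a quadrat equals the
    quadrat's (scaled) area.

    Raises
    ------
    ValueError
        For an empty pattern, whose intensity rescaling is undefined.
    """
    if pattern.n == 0:
        raise ValueError("cannot rescale an empty pattern: intensity is undefined")
    s = math.sqrt(pattern.landscape.area / pattern.n)
    scaled = PointPattern(
        coords=pattern.coords / s,
        landscape=Landscape(pattern.landscape.width / s, pattern.landscape.height / s),
    )
    return scaled, s


def unscale_coords(coords: np.ndarray, scale: float) -> np.ndarray:
    """Invert :func:`rescale_to_unit_intensity` on raw coordinates."""
    return np.asarray(coords, dtype=float) * scale
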