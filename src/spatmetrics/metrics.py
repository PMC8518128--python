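"""Empirical estimation of the five spatial metrics from a point pattern.

Everything here works in whatever units the pattern carries; for comparison
with the theory engine, rescale the pattern to unit intensity first
(:func:`spatmetrics.landscape.rescale_to_unit_intensity`) so that quadrat
areas, distances and gaps are in scaled units.

Quadrat-based metrics (Taylor's Law, occupancy) use a deterministic
origin-anchored grid of non-overlapping squares, discarding partial tiles;
random quadrat placement is available as an option.  The O-ring statistic is
an annulus-binned, edge-corrected neighbour density; translation correction
is the default for rectangular windows, with a guard-buffer alternative.
Two-plot metrics enumerate axis-aligned pairs of equal squares separated by a
nearest-edge gap D along either axis, pooling both orientations (isotropy
makes orientation irrelevant in expectation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .landscape import PointPattern

__all__ = [
    "MetricCurve",
    "quadrat_counts",
    "taylor_curve",
    "occupancy_curve",
    "oring_estimate",
    "two_plot_pairs",
    "two_plot_cov",
    "two_plot_turnover",
]

log = logging.getLogger(__name__)

METRIC_KINDS = ("taylor", "occupancy", "oring", "twoplot_cov", "turnover")


@dataclass
class MetricCurve:
    """One spatial metric evaluated on a grid of areas, distances or gaps.

    ``abscissa`` is plot area A for taylor/occupancy, annulus midpoint r for
    oring, and nearest-edge gap D for the two-plot metrics (which also carry
    the fixed ``plot_side``).  ``support`` counts the quadrats, point pairs
    or plot pairs behind each value; ``mean`` stores the companion quadrat
    mean for Taylor curves.
    """

    kind: str
    abscissa: np.ndarray
    ordinate: np.ndarray
    support: np.ndarray
    plot_side: float | None = None
    mean: np.ndarray | None = None
    scale_factor: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in METRIC_KINDS:
            raise ValueError(f"unknown metric kind {self.kind!r}")
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.ordinate = np.asarray(self.ordinate, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        if self.mean is not None:
            self.mean = np.asarray(self.mean, dtype=float)
        if self.abscissa.size and np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("abscissa must be strictly increasing")
        if self.abscissa.shape != self.ordinate.shape != self.support.shape:
            raise ValueError("abscissa, ordinate and support must have equal length")
        if self.kind in ("twoplot_cov", "turnover") and self.plot_side is None:
            raise ValueError(f"{self.kind} curves require plot_side")
        if self.kind in ("occupancy", "turnover") and self.ordinate.size:
            if self.ordinate.min() < 0 or self.ordinate.max() > 1:
                raise ValueError(f"{self.kind} ordinate must lie in [0, 1]")


# ---------------------------------------------------------------------------
# quadrat counts
# ---------------------------------------------------------------------------

def quadrat_counts(
    pattern: PointPattern,
    side: float,
    scheme: str = "grid",
    n_random: int = 0,
    seed: int | None = None,
) -> np.ndarray:
    """Counts of points in square quadrats of the given side.

    ``scheme='grid'`` tiles the window with non-overlapping squares anchored
    at the origin (partial tiles discarded; deterministic).  ``scheme='random'``
    places ``n_random`` uniformly located squares entirely inside the window.
    """
    w, h = pattern.landscape.width, pattern.landscape.height
    if side > min(w, h):
        raise ValueError(f"quadrat side {side} exceeds window dimensions {w} x {h}")
    if not side > 0:
        raise ValueError("quadrat side must be positive")
    xy = pattern.coords
    if scheme == "grid":
        nx, ny = int(w / side + 1e-9), int(h / side + 1e-9)
        ix = np.floor(xy[:, 0] / side).astype(int)
        iy = np.floor(xy[:, 1] / side).astype(int)
        keep = (ix < nx) & (iy < ny)
        flat = ix[keep] * ny + iy[keep]
        return np.bincount(flat, minlength=nx * ny)
    if scheme == "random":
        if n_random < 1:
            raise ValueError("random scheme needs n_random >= 1")
        rng = np.random.default_rng(seed)
        x0 = rng.uniform(0.0, w - side, size=n_random)
        y0 = rng.uniform(0.0, h - side, size=n_random)
        inx = (xy[:, 0][None, :] >= x0[:, None]) & (xy[:, 0][None, :] < (x0 + side)[:, None])
        iny = (xy[:, 1][None, :] >= y0[:, None]) & (xy[:, 1][None, :] < (y0 + side)[:, None])
        return (inx & iny).sum(axis=1)
    raise ValueError(f"unknown quadrat scheme {scheme!r}")


def _per_side_counts(pattern, sides, min_quadrats=2):
    kept_sides, all_counts = [], []
    for side in sides:
        counts = quadrat_counts(pattern, side)
        if counts.size < min_quadrats:
            warnings.warn(
                f"side {side}: only {counts.size} quadrat(s), dropping this area",
                stacklevel=3,
            )
            continue
        kept_sides.append(side)
        all_counts.append(counts)
    return kept_sides, all_counts


def taylor_curve(pattern: PointPattern, sides) -> MetricCurve:
    """Empirical Taylor's Law: quadrat-count variance against plot area.

    For each side the ordinate is the unbiased (n-1 divisor) sample variance
    of grid quadrat counts and ``mean`` stores the companion sample mean, so
    that the variance-mean pairing of Taylor's Law is preserved.
    """
    sides, counts = _per_side_counts(pattern, np.sort(np.asarray(sides, float)))
    areas = np.array([s**2 for s in sides])
    return MetricCurve(
        kind="taylor",
        abscissa=areas,
        ordinate=np.array([c.var(ddof=1) for c in counts]),
        support=np.array([c.size for c in counts]),
        mean=np.array([c.mean() for c in counts]),
    )


def occupancy_curve(pattern: PointPattern, sides) -> MetricCurve:
    """Empirical occupancy-area curve: fraction of grid quadrats occupied."""
    sides, counts = _per_side_counts(pattern, np.sort(np.asarray(sides, float)))
    return MetricCurve(
        kind="occupancy",
        abscissa=np.array([s**2 for s in sides]),
        ordinate=np.array([(c > 0).mean() for c in counts]),
        support=np.array([c.size for c in counts]),
    )


# ---------------------------------------------------------------------------
# O-ring / neighborhood density
# ---------------------------------------------------------------------------

def oring_estimate(
    pattern: PointPattern, r_edges, correction: str = "translation"
) -> MetricCurve:
    """Annulus-binned neighborhood density Omega(r), edge corrected.

    For each annulus [e_i, e_{i+1}) the estimate is the edge-corrected mean
    number of other points at that distance per point, divided by annulus
    area times intensity; at unit intensity this is a binned pair-correlation
    estimate.

    ``correction='translation'`` weights each ordered pair by
    |W| / |W intersect W_shift| (standard for rectangular windows);
    ``correction='buffer'`` averages raw neighbour counts over points farther
    than max(r_edges) from every boundary, for which the estimator satisfies
    the exact neighbour-count identity sum_bins Omega_hat * annulus_area =
    mean neighbours within r_max.
    """
    r_edges = np.asarray(r_edges, dtype=float)
    if r_edges.ndim != 1 or r_edges.size < 2 or np.any(np.diff(r_edges) <= 0):
        raise ValueError("r_edges must be an increasing 1D array of bin boundaries")
    if pattern.n < 2:
        raise ValueError("O-ring estimation needs at least 2 points")
    xy = pattern.coords
    w, h = pattern.landscape.width, pattern.landscape.height
    lam = pattern.intensity
    r_max = r_edges[-1]
    areas = np.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)
    mids = 0.5 * (r_edges[:-1] + r_edges[1:])

    dx = xy[:, 0][:, None] - xy[:, 0][None, :]
    dy = xy[:, 1][:, None] - xy[:, 1][None, :]
    d = np.hypot(dx, dy)
    iu = ~np.eye(pattern.n, dtype=bool)

    if correction == "translation":
        sel = iu & (d < r_max)
        dsel = d[sel]
        wts = (w * h) / ((w - np.abs(dx[sel])) * (h - np.abs(dy[sel])))
        idx = np.searchsorted(r_edges, dsel, side="right") - 1
        ok = (idx >= 0) & (idx < mids.size)
        sums = np.bincount(idx[ok], weights=wts[ok], minlength=mids.size)
        pair_n = np.bincount(idx[ok], minlength=mids.size)
        ordinate = sums / (pattern.n * lam * areas)
        support = pair_n
    elif correction == "buffer":
        interior = (
            (xy[:, 0] >= r_max)
            & (xy[:, 0] <= w - r_max)
            & (xy[:, 1] >= r_max)
            & (xy[:, 1] <= h - r_max)
        )
        m = int(interior.sum())
        if m == 0:
            raise ValueError(
                f"buffer correction: no points farther than r_max={r_max} from the boundary"
            )
        # neighbours of interior points (excluding self-distances)
        dmat = d[interior]
        self_cols = np.flatnonzero(interior)
        mask = np.ones_like(dmat, dtype=bool)
        mask[np.arange(m), self_cols] = False
        dvals = dmat[mask]
        idx = np.searchsorted(r_edges, dvals[dvals < r_max], side="right") - 1
        ok = idx >= 0
        pair_n = np.bincount(idx[ok], minlength=mids.size)
        ordinate = pair_n / (m * lam * areas)
        support = pair_n
    else:
        raise ValueError(f"unknown edge correction {correction!r}")
    return MetricCurve(
        kind="oring",
        abscissa=mids,
        ordinate=ordinate,
        support=support,
        meta={"correction": correction, "r_edges": r_edges.tolist()},
    )


# ---------------------------------------------------------------------------
# two-plot metrics
# ---------------------------------------------------------------------------

def _raster_counts(pattern, side, x0, y0, nx, ny):
    """Counts in an nx-by-ny raster of squares anchored at (x0, y0)."""
    xy = pattern.coords
    ix = np.floor((xy[:, 0] - x0) / side).astype(int)
    iy = np.floor((xy[:, 1] - y0) / side).astype(int)
    keep = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (xy[:, 0] >= x0) & (xy[:, 1] >= y0)
    return np.bincount(ix[keep] * ny + iy[keep], minlength=nx * ny).reshape(nx, ny)


def two_plot_pairs(
    pattern: PointPattern, side: float, gaps
) -> dict[float, np.ndarray]:
    """Joint counts (n, n') for pairs of equal square plots at each gap D.

    Pairs are enumerated on an origin-anchored raster: the first plot sits at
    (i*side, j*side), the second at nearest-edge gap D along the +x axis
    (horizontal orientation) or +y axis (vertical); both orientations are
    pooled, each unordered placement contributing one (n, n') pair.  Gaps
    with no feasible placement are dropped with a warning.
    """
    if not side > 0:
        raise ValueError("plot side must be positive")
    w, h = pattern.landscape.width, pattern.landscape.height
    out: dict[float, np.ndarray] = {}
    for D in np.asarray(gaps, dtype=float):
        if D < 0:
            raise ValueError("gaps must be non-negative")
        pairs = []
        # horizontal separation: first plot column i needs i*side + 2*side + D <= w
        n1x = int(np.floor((w - 2 * side - D) / side + 1e-9)) + 1
        ny = int(h / side + 1e-9)
        if n1x >= 1 and ny >= 1:
            c1 = _raster_counts(pattern, side, 0.0, 0.0, n1x, ny)
            c2 = _raster_counts(pattern, side, side + D, 0.0, n1x, ny)
            pairs.append(np.column_stack([c1.ravel(), c2.ravel()]))
        # vertical separation
        n1y = int(np.floor((h - 2 * side - D) / side + 1e-9)) + 1
        nx = int(w / side + 1e-9)
        if n1y >= 1 and nx >= 1:
            c1 = _raster_counts(pattern, side, 0.0, 0.0, nx, n1y)
            c2 = _raster_counts(pattern, side, 0.0, side + D, nx, n1y)
            pairs.append(np.column_stack([c1.ravel(), c2.ravel()]))
        if not pairs:
            warnings.warn(f"gap D={D}: no feasible plot pair in the window, dropped",
                          stacklevel=2)
            continue
        out[float(D)] = np.vstack(pairs)
    return out


def two_plot_cov(pattern: PointPattern, side: float, gaps) -> MetricCurve:
    """Two-plot Taylor's Law variant: covariance of joint counts against gap D.

    The covariance at each D is symmetrised: both counts of an unordered pair
    are centred on the pooled mean of all counts at that D, with an n-1
    divisor, so that exchanging the two plots leaves the estimate unchanged.
    """
    pair_map = two_plot_pairs(pattern, side, gaps)
    ds = np.array(sorted(pair_map))
    cov, supp = [], []
    for D in ds:
        nn = pair_map[D].astype(float)
        m = nn.mean()
        cov.append(float(((nn[:, 0] - m) * (nn[:, 1] - m)).sum() / (nn.shape[0] - 1)))
        supp.append(nn.shape[0])
    return MetricCurve(
        kind="twoplot_cov",
        abscissa=ds,
        ordinate=np.array(cov),
        support=np.array(supp),
        plot_side=side,
    )


def two_plot_turnover(pattern: PointPattern, side: float, gaps) -> MetricCurve:
    """Two-plot turnover: P(both plots occupied) / P(one plot occupied).

    The single-plot occupancy in the denominator is estimated from the same
    pooled plot placements that form the pairs.  Sampling noise can push the
    ratio slightly above 1; such values are clipped to [0, 1] with a warning.
    """
    pair_map = two_plot_pairs(pattern, side, gaps)
    ds = np.array(sorted(pair_map))
    vals, supp = [], []
    for D in ds:
        nn = pair_map[D]
        psi = float((nn > 0).mean())
        if psi == 0.0:
            raise ValueError(
                f"gap D={D}: no occupied plot among placements, turnover undefined"
            )
        both = float(((nn[:, 0] > 0) & (nn[:, 1] > 0)).mean())
        t = both / psi
        if t > 1.0:
            warnings.warn(
                f"gap D={D}: turnover estimate {t:.4f} > 1 clipped (sampling noise)",
                stacklevel=2,
            )
            t = 1.0
        vals.append(t)
        supp.append(nn.shape[0])
    return MetricCurve(
        kind="turnover",
        abscissa=ds,
        ordinate=np.array(vals),
        support=np.array(supp),
        plot_side=side,
    )
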