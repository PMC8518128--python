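"""Point-process simulators: complete spatial randomness and the Thomas process.

The Thomas process is a Poisson cluster process: parent centres follow a
homogeneous Poisson process of intensity ``rho``, each parent receives a
Poisson(``mu_cluster``) number of offspring, and offspring are displaced from
their parent by independent Normal(0, ``sigma_cluster**2``) shifts in each
axis.  Its pair correlation function is Gaussian,

    g(r) = exp(-r^2 / (4 sigma^2)) / (4 pi rho sigma^2) + 1,

so in unit-intensity scaled units the process realises the Gaussian
second-order intensity family with amplitude ``alpha = 1/(4 pi rho sigma^2)``
and range parameter ``beta = 1/(4 sigma^2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .landscape import Landscape, PointPattern

__all__ = [
    "ThomasParams",
    "simulate_csr",
    "simulate_thomas",
    "thomas_from_alpha_beta",
    "alpha_beta_from_thomas",
    "simulate_community",
    "replicate_seed",
]

#: parents are simulated on a window buffered by this many sigma_cluster on
#: each side, bounding offspring edge-deficit bias below Normal tail mass ~1e-6
PARENT_BUFFER_SIGMAS = 5.0

#: guard against alpha -> 0 degenerating into an unboundedly dense parent process
DEFAULT_RHO_CEILING = 1e4


@dataclass(frozen=True)
class ThomasParams:
    """Thomas process parameters in the landscape's own length units."""

    rho: float  # cluster-centre intensity, centres per unit area
    mu_cluster: float  # mean offspring per cluster
    sigma_cluster: float  # within-cluster displacement SD, length units

    def __post_init__(self) -> None:
        if not (self.rho > 0 and self.mu_cluster > 0 and self.sigma_cluster > 0):
            raise ValueError(f"Thomas parameters must all be positive, got {self}")

    def expected_n(self, landscape: Landscape) -> float:
        return self.rho * self.mu_cluster * landscape.area


def replicate_seed(master_seed: int, replicate: int) -> int:
    """Counter-based per-replicate seed so replicate r is reproducible alone."""
    ss = np.random.SeedSequence(int(master_seed))
    child = ss.spawn_key + (int(replicate),)
    return int(np.random.SeedSequence(int(master_seed), spawn_key=child).generate_state(1)[0] % (2**31 - 1))


def simulate_csr(expected_n: float, landscape: Landscape, seed: int) -> PointPattern:
    """Homogeneous Poisson (CSR) pattern with Poisson(expected_n) points."""
    if not expected_n > 0:
        raise ValueError(f"expected_n must be positive, got {expected_n}")
    rng = np.random.default_rng(seed)
    n = rng.poisson(expected_n)
    xy = rng.uniform(0.0, 1.0, size=(n, 2)) * [landscape.width, landscape.height]
    return PointPattern(xy, landscape)


def simulate_thomas(
    params: ThomasParams, landscape: Landscape, seed: int, fixed_n: int | None = None
) -> PointPattern:
    """Simulate a Thomas cluster pattern inside ``landscape``.

    Parents are placed on a window buffered by ``PARENT_BUFFER_SIGMAS * sigma``
    on every side so that clusters centred just outside the window still
    contribute offspring; only offspring falling inside the unbuffered window
    are retained.

    If ``fixed_n`` is given the realisation is thinned (or re-simulated and
    topped up) to exactly that many points; the unconditioned process is the
    default.
    """
    rng = np.random.default_rng(seed)
    buf = PARENT_BUFFER_SIGMAS * params.sigma_cluster
    bw, bh = landscape.width + 2 * buf, landscape.height + 2 * buf
    n_parents = rng.poisson(params.rho * bw * bh)
    parents = rng.uniform(0.0, 1.0, size=(n_parents, 2)) * [bw, bh] - buf
    n_off = rng.poisson(params.mu_cluster, size=n_parents)
    centres = np.repeat(parents, n_off, axis=0)
    xy = centres + rng.normal(0.0, params.sigma_cluster, size=centres.shape)
    inside = (
        (xy[:, 0] >= 0)
        & (xy[:, 0] <= landscape.width)
        & (xy[:, 1] >= 0)
        & (xy[:, 1] <= landscape.height)
    )
    xy = xy[inside]
    if fixed_n is not None:
        while xy.shape[0] < fixed_n:  # top up from extra independent clusters
            extra = simulate_thomas(params, landscape, int(rng.integers(2**31 - 1)))
            xy = np.vstack([xy, extra.coords])
        keep = rng.choice(xy.shape[0], size=fixed_n, replace=False)
        xy = xy[np.sort(keep)]
    return PointPattern(xy, landscape)


def thomas_from_alpha_beta(
    alpha: float,
    beta: float,
    expected_n: float,
    landscape: Landscape,
    rho_ceiling: float = DEFAULT_RHO_CEILING,
) -> ThomasParams:
    """Invert (alpha, beta) in scaled units into Thomas parameters in landscape units.

    ``alpha`` and ``beta`` parameterise the scaled-unit pair correlation
    ``g(r) = alpha * exp(-beta r^2) + 1``; the inversion uses
    ``sigma_scaled^2 = 1/(4 beta)`` and ``rho_scaled = beta / (pi alpha)``,
    then converts through the unit-intensity scale factor
    ``s = sqrt(area / expected_n)``.  ``mu_cluster`` is set so the expected
    number of points in the window equals ``expected_n``.
    """
    if not (alpha > 0 and beta > 0 and expected_n > 0):
        raise ValueError("alpha, beta and expected_n must all be positive")
    sigma2_scaled = 1.0 / (4.0 * beta)
    rho_scaled = 1.0 / (4.0 * math.pi * alpha * sigma2_scaled)  # = beta/(pi alpha)
    if rho_scaled > rho_ceiling:
        raise ValueError(
            f"alpha={alpha} implies parent intensity {rho_scaled:.3g} above the "
            f"ceiling {rho_ceiling:.3g}; the process is degenerating to CSR"
        )
    s = math.sqrt(landscape.area / expected_n)
    rho = rho_scaled / s**2
    sigma = math.sqrt(sigma2_scaled) * s
    mu_cluster = expected_n / (rho * landscape.area)
    return ThomasParams(rho=rho, mu_cluster=mu_cluster, sigma_cluster=sigma)


#: log-log gradient of (alpha, beta) against abundance, anchored on the
#: abundance-tertile medians of Thomas fits to the Barro Colorado Island
#: census: (n, alpha, beta) = (108, 4.5, 3.8), (432, 2.7, 0.8), (1856, 1.0, 0.1)
_COMMUNITY_LOGN_RANGE = (math.log(100.0), math.log(2000.0))
_COMMUNITY_ALPHA_FIT = (4.061, -0.530)  # ln alpha = a0 + a1 ln n
_COMMUNITY_BETA_FIT = (7.401, -1.280)  # ln beta = b0 + b1 ln n
_COMMUNITY_SCATTER = 0.35  # lognormal scatter around the gradient


def simulate_community(
    n_species: int,
    landscape: Landscape,
    seed: int,
    scatter: float = _COMMUNITY_SCATTER,
) -> tuple[dict[str, PointPattern], "np.ndarray"]:
    """A synthetic multi-species community of Thomas-process species.

    Species abundances are log-uniform over [100, 2000] and each species'
    scaled-unit (alpha, beta) follows the empirical tropical-forest gradient
    of clustering against abundance (rarer species are more aggregated at
    shorter range), with independent lognormal scatter.  Returns the pattern
    for each species plus a structured array of the true parameters.
    """
    rng = np.random.default_rng(seed)
    patterns: dict[str, PointPattern] = {}
    truth = np.zeros(
        n_species, dtype=[("name", "U16"), ("n", int), ("alpha", float), ("beta", float)]
    )
    for i in range(n_species):
        ln_n = rng.uniform(*_COMMUNITY_LOGN_RANGE)
        n = int(round(math.exp(ln_n)))
        alpha = math.exp(
            _COMMUNITY_ALPHA_FIT[0] + _COMMUNITY_ALPHA_FIT[1] * ln_n
            + rng.normal(0.0, scatter)
        )
        beta = math.exp(
            _COMMUNITY_BETA_FIT[0] + _COMMUNITY_BETA_FIT[1] * ln_n
            + rng.normal(0.0, scatter)
        )
        params = thomas_from_alpha_beta(alpha, beta, n, landscape)
        name = f"sp{i:03d}"
        patterns[name] = simulate_thomas(
            params, landscape, int(rng.integers(2**31 - 1))
        )
        truth[i] = (name, n, alpha, beta)
    return patterns, truth


def alpha_beta_from_thomas(
    params: ThomasParams, expected_n: float, landscape: Landscape
) -> tuple[float, float]:
    """Forward map to scaled-unit (alpha, beta); inverse of thomas_from_alpha_beta."""
    s = math.sqrt(landscape.area / expected_n)
    sigma2_scaled = (params.sigma_cluster / s) ** 2
    rho_scaled = params.rho * s**2
    alpha = 1.0 / (4.0 * math.pi * rho_scaled * sigma2_scaled)
    beta = 1.0 / (4.0 * sigma2_scaled)
    return alpha, beta
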