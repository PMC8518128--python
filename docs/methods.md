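# Methods

## The framework

`spatmetrics` implements a single mathematical framework that links five
widely used single-species spatial metrics, so that the parametric form of
any one of them determines the other four:

1. **Taylor's Law** — the quadrat-count variance σ²(A) as a function of plot
   area A;
2. the **occupancy–area curve** Ψ(A) — the probability that a plot of area A
   contains at least one individual;
3. the **neighborhood density function (O-ring)** Ω(r) — the expected point
   density at distance r from a typical individual, equal to the pair
   correlation function at unit intensity;
4. the **two-plot Taylor's Law** C(A, D) — the covariance of abundances in two
   equal plots with nearest-edge gap D;
5. **two-plot turnover** T(A, D) — the probability that both plots are
   occupied divided by single-plot occupancy (equivalently, conditional
   occupancy given the other plot is occupied).

The link runs through three intermediate statistics of a point pattern
assumed *orderly* (no coincident points), *homogeneous* and *isotropic*: the
first-order intensity λ, the second-order intensity λ₂(r), and the quadrat
count distribution P(n | A).  All internal computations use length units
scaled so that λ = 1 (`rescale_to_unit_intensity`; scale factor
s = √(area/n)), which makes the expected count in a plot equal its area,
μ(A) = A, and removes abundance from every formula.  I/O layers convert at
the boundary and record s in output metadata.

The moment identities are

    σ²(A) − μ + μ² = ∬_L∬_L λ₂(r) dx₁ dx₂              (within one plot)
    C(A, D) + μ²   = ∬_L∬_L′ λ₂(r) dx₁ dx₂             (across two plots)

with Ω(r) = λ₂(r)/λ.  The occupancy layer adds one distributional
assumption: quadrat counts are negative binomial, moment-matched to
(μ, σ²), giving

    Ψ(A) = 1 − (A/σ²)^(A²/(σ²−A))

and, for two plots, a bivariate negative binomial built as N = U + S,
N′ = V + S from three independent NB components sharing one success
probability p (see below), giving

    T(A, D) = 2 + (1/Ψ)[(A/σ²)^(A²(2σ²−C)/(σ²(σ²−A))) − 1].

## Parametric families (`theory`)

**Gaussian second-order intensity** λ₂(r) = α·e^(−βr²) + 1.  α ≥ 0 is the
dimensionless excess aggregation at r = 0 and β > 0 an inverse squared
correlation range (scaled units); α = 0 is exact complete spatial
randomness (CSR), handled as a dedicated branch to avoid 0/0 in the
occupancy formulas.  This family is the pair correlation of the Thomas
cluster process, with α = 1/(4πρσ²), β = 1/(4σ²).  Both moment integrals
factorise over axes and have exact erf closed forms; for the covariance the
plot geometry enters through the plot *side* L = √A:

    σ²(A)  = (α/β²)[√(πβA)·erf√(βA) + e^(−βA) − 1]² + A
    C(A,D) = α · J(A) · K(A, D)
    J      = (1/β)[√(πβA)·erf√(βA) + e^(−βA) − 1]
    K      = (√π/2√β)[D·erf(√β·D)]″ + (1/2β)[e^(−βD²)]″

where [f(D)]″ denotes the second difference f(D) − 2f(D+L) + f(D+2L).
Whether lengths enter these expressions as A or √A is easy to get wrong; we
fixed the convention by requiring exact agreement with an independent
numerical evaluation of the moment integrals (see *Numerical oracles*), and
the closed forms agree with that oracle to better than 10⁻⁸ relative.

**Power-law Taylor's Law** σ²(A) = a·A^b.  In one dimension the implied
O-ring and covariance are exact:

    Ω(r)   = ½ab(b−1)·r^(b−2) + 1          (r > 0)
    C(A,D) = ½a[D^b − 2(D+A)^b + (D+2A)^b]

In two dimensions only an approximation is available, valid for
1 < b < 2:  Ω(r) ≈ c·r^(2(b−2)) + 1 with

    c = a·b(b−1)(2b−1) / (π(2b−1) − 4(b−1)).

Pushing this Ω back through the variance integral reproduces a·A^b up to a
constant factor in A (about +4% at b = 1.51) — the documented error of the
approximation.  The 2D covariance uses a quasi-one-dimensional expansion of
the cross integral of c·r^(−γ), γ = 2(2−b): a leading second-difference
term in (D, D+√A, D+2√A) plus a lateral-spread correction of relative order
(A/D²); the correction diverges at D = 0 and is applied only for D > 0.
Accuracy improves with D/√A (a few percent once D exceeds the plot side);
quantitative users should validate against the numerical oracle at their
(A, D).

Both power-law families carry a formal Dirac atom at r = 0 in λ₂
(coefficient −1), which contributes exactly −μ to the moment integral; the
atom is bookkept analytically and never integrated numerically, and
pointwise Ω evaluation excludes it (r > 0 required).

## The bivariate negative binomial (`negbin`)

The standard bivariate NB cannot carry an arbitrary covariance given its
marginal moments, so the joint count is constructed from three independent
NB components U, V, S with a *shared* success probability p: individuals
unique to plot 1, unique to plot 2, and common to both.  With
k = μ²/(σ²−μ), p = μ/σ²:

    k_s = k·C/σ²,   k_u = k_v = k − k_s,
    P(0,0) = p^(k_u+k_v+k_s) = p^(2k − k_s).

Sharing p is the unique choice that keeps both marginals exactly NB(k, p)
(convolution closure) and makes the construction's turnover identical to
the closed form above — an identity the tests verify to 10⁻¹² relative over
a randomized parameter sweep, alongside a Monte Carlo sampler cross-check.
The construction is a derivation forced by the closed form, not a
transcription of any published parameterization.  The covariance must lie
in [0, σ²]; negative or super-marginal covariances are rejected (optional
explicit clamping for noisy empirical moments).  At σ² → μ the moment
inversion is 0/0; within |σ²−μ| ≤ 10⁻⁹μ the analytic Poisson limit is used
(Ψ → 1 − e^(−μ), P(0,0) → e^(−(2μ−C))), and the log-domain evaluation
`−μ²·log1p((σ²−μ)/μ)/(σ²−μ)` keeps the approach to that boundary stable.

## Empirical estimators (`metrics`)

* **Quadrat counts**: deterministic origin-anchored grid of non-overlapping
  squares, partial tiles discarded (random placement available).  Sample
  variance and covariance use the n−1 divisor.  Plot sides with fewer than
  two quadrats are dropped with a warning.
* **O-ring**: annulus-binned neighbour density.  Default edge correction is
  the translation correction (each ordered pair weighted by
  |W|/|W ∩ W_shift|), standard for rectangular windows; a guard-`buffer`
  alternative restricts to points ≥ r_max from the boundary, for which
  Σ_bins Ω̂ · annulus area · λ equals the mean neighbour count exactly.
* **Two-plot metrics**: axis-aligned pairs of equal squares, separation
  along one axis, D = nearest-edge gap, both orientations pooled (isotropy
  makes orientation irrelevant in expectation).  The default plot side is
  25 m in original units, converted per species.  Turnover divides the
  fraction of pairs with both plots occupied by the occupancy of the pooled
  placements, clipping values above 1 (sampling noise) with a warning.

## Fitting (`fitting`)

**Per-metric Gaussian fits** minimise squared residuals over
α ∈ [0, 10³], β ∈ (10⁻⁶, 10³] with a 6×6 log-grid multi-start.  Occupancy
and turnover predictions compose the NB layer on the Gaussian moments, so
the NB assumption enters those two fits only.  Taylor curves are fitted on
log σ², not raw σ²: the ordinate spans orders of magnitude across plot
areas and raw residuals would be dominated by the largest plots, discarding
the small-area information that separates α from the large-area ratio α/β
(with raw residuals the fitted parameters carry essentially no rank
information across species; on log scale they recover true ranks at
Spearman ρ ≈ 0.9).  All other metrics use raw residuals.

**Minimum contrast on the pair correlation** fits the Thomas process: the
pcf is kernel-estimated (Epanechnikov kernel, Stoyan bandwidth 0.15/√λ,
translation correction, pair intensity n(n−1)/|W|², 512-point grid), and
(ρ, σ²) minimise ∫₀^rmax (ĝ^q − g^q)² dr with the conventional q = 0.25 and
r_max = min(window)/4.  These defaults mirror the standard point-process
toolchain.  Fits whose cluster scale falls below half the kernel bandwidth
(or α < 10⁻³) are flagged degenerate — there is no resolvable clustering
signal, as on CSR input.  This estimator is deliberately *not* unbiased at
small n: the replicate study below reports median fitted parameters above
the targets (e.g. β 3.8 → ≈4.8 at n ≈ 108), reproducing the recovery bias
expected of this method; predictions for the simulated species therefore
use the recovered parameters (target parameters for the high-abundance
species, where recovery is accurate).

## Numerical oracles

The generic moment integrals are evaluated independently of the closed
forms.  The within-square 4D integral reduces through the square
line-picking density (the classical distance distribution between two
uniform points in a square) to a 1D adaptive quadrature, accurate to
~10⁻⁹ relative.  The cross-square integral reduces to a 2D integral over
the separation vector weighted by triangular overlap densities, evaluated
by tensor Gauss–Legendre panels split at the weight kinks (deterministic,
~10⁻¹⁰ for smooth λ₂); a seeded Monte Carlo alternative (10⁶ pairs by
default) remains available for arbitrary λ₂.  Quadrature is the default
because the oracle-equivalence tests demand 10⁻⁴ relative agreement,
beyond Monte Carlo noise at that sample size.

## The simulators and what the synthetic data do not show

`simulate_thomas` draws parents on a window buffered by 5σ per side
(offspring edge-deficit below Normal tail mass ~10⁻⁶), Poisson offspring
counts, isotropic Gaussian scatter; total abundance is Poisson-random, not
conditioned (a `fixed_n` option thins/tops up on request, logged as
non-default).  Per-replicate seeds derive from the master seed through a
counter-based SeedSequence scheme, so any replicate is reproducible in
isolation.

The replicate study (`run_simulation_study`) uses three idealized species
whose (n, α, β) are the abundance-tertile medians of Thomas fits to the
Barro Colorado Island 500 m × 1000 m census: low (108, 4.5, 3.8), medium
(432, 2.7, 0.8), high (1856, 1.0, 0.1); 200 replicates each at full scale.
Metric curves are measured in species-level scaled units (scale factor from
the *expected* n, common across replicates, so per-abscissa medians are
well defined); the minimum-contrast fit rescales each replicate by its
*realised* n, as one would with data.  Default measurement grids: quadrat
sides (10, 25, 50, 100, 175, 250) m, 25 O-ring bins up to min(window)/4,
gaps (0, 12.5, 25, 50, 100, 150, 200) m at the 25 m plot.

The synthetic community generator (`simulate_community`) emulates the
empirical gradient of clustering against abundance — log-uniform n in
[100, 2000] with log-linear (α, β) declining in n through the three tertile
anchors, lognormal scatter 0.35.  It does *not* emulate habitat
heterogeneity, dispersal anisotropy, inter-species dependence, or
non-Gaussian within-cluster kernels; passing tests on these communities
show that the estimation and correlation machinery works when the model
family is correct, not that real species follow a Gaussian λ₂.

## Known limitations

* The NB quadrat-count layer is an approximation for cluster processes.  In
  the replicate study its occupancy predictions sit systematically *above*
  the simulation medians for all three species (the simulated patterns are
  more aggregated than a negative binomial allows).  For turnover the error
  changes sign with gap and plot area: predictions fall *below* the medians
  at gaps ≲ 50 m for the low and medium species and above them at larger
  gaps and for the high species.  This sign structure persists when the NB
  layer is fed the true pooled joint-count moments instead of fitted
  parameters, so it is a property of the approximation itself, not of the
  estimation pipeline; the bias table produced by the study reports it
  rather than hiding it.
* The 2D power-law forms are approximations with the validity limits noted
  above; b must lie strictly inside (1, 2).
* Pairwise-distance computations are O(n²) and comfortable to a few
  thousand points per species; very abundant species need thinning.
* Windows are axis-aligned rectangles; no irregular windows, marks beyond
  a species label, or inhomogeneous intensities.
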