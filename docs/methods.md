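# Methods

## Model

Condensates are modelled as spheres of volume V = (4/3)πR³ in a cubic
box of side L with periodic boundaries. Each sphere follows a
fractional Brownian motion (fBm) trajectory with anomalous exponent α,
i.e. ensemble MSD ⟨r²⟩ = 2dDτ^α in d = 3; an fBm with that MSD has
Hurst exponent H = α/2. α = 1 is ordinary diffusion; α < 1 represents
the subdiffusion of bodies embedded in chromatin or other viscoelastic
media. Mobility depends on size as D = D₀/R^γ; γ = 1 is the
Stokes–Einstein relation, γ < 1 weakens the size penalty, and γ < 0
makes spheres move faster as they grow.

At every step each sphere advances one precomputed fBm increment scaled
by (R_ref/R)^(γ/2), where R_ref is the radius of a unit-volume sphere,
so that displacement variance scales exactly as D ∝ R^(−γ). Any two
spheres whose minimum-image distance falls below R₁ + R₂ merge
instantly: the pair is replaced by one sphere of volume V₁ + V₂ at the
volume-weighted centre of mass (computed in one parent's frame and then
wrapped). Overlapping pairs are resolved one at a time by uniform
random selection among currently overlapping pairs, iterating until no
overlap remains, so chains created by a merger are merged in the same
step. The merged sphere continues the trajectory of its larger parent
(a seeded switch selects random inheritance instead; the distribution
statistics are insensitive to the choice). Coalescence is instantaneous
and there is no Ostwald ripening, fragmentation, or hydrodynamic
interaction.

Two nucleation scenarios:

* **Quench**: N spheres with volumes uniform on [1, 2] are placed
  uniformly at random; initial overlaps are merged away before step 0.
  The box satisfies v_f = N·v̄₀/L³ for a target volume fraction v_f.
  Total volume is conserved exactly for the whole run.
* **Injection**: the box starts empty and sphere k enters at step
  ⌊k/J⌋ — J = 0.25 means one sphere every fourth step, J = 4 means four
  per step — until N spheres have been injected; the run ends at the
  last injection.

Time is measured in Monte Carlo steps and lengths in units where the
initial mean volume is 1.5; all rates (J, K, j, ρ) are in these units.

### Synthesis of fBm

Increments are fractional Gaussian noise generated by circulant
embedding (Davies–Harte): the fGn autocovariance is embedded in a
circulant matrix, its eigenvalues obtained by FFT, and one FFT of
Hermitian complex Gaussian weights yields a series with exactly the
target covariance. The three spatial components are independent
streams (isotropy); H = 0.5 short-circuits to i.i.d. normals.
Trajectories are synthesized for a sphere's full lifetime up front so
the long-range increment correlations survive mergers. The per-
dimension RMS single-step displacement at R = R_ref is the parameter
Δr (`base_step`), giving D₀ = Δr²/2.

### Collision detection

Overlap candidates come from a periodic k-d tree queried at twice the
current maximum radius (cell-list complexity); an O(n²) minimum-image
audit is retained as a test oracle and the two detectors produce
bit-identical merger sequences at equal seeds. When 2R_max approaches
L/2 the implementation falls back to the O(n²) path.

## Kernel framework

The Smoluchowski coagulation kernel K(V₁,V₂) = 4π(D₁+D₂)(R₁+R₂) sets
the relative collision rates: constant for equal-size Stokes–Einstein
spheres ("equal-opportunity" mergers → exponential size distribution),
growing as R₁/R₂ for very unequal pairs or for γ < 1 (preferential
attachment → power laws).

**Empirical kernel.** Every merger is logged with the instantaneous
number densities f(V₁), f(V₂) of the partners' size classes
(logarithmic bins, factor 1.5, counted over the alive population at the
event). The estimator sums 1/(f(V₁)f(V₂)) per bin pair, doubles
same-bin weights (the pair rate within one class is Kf²/2), averages
over replicates and normalizes by system volume and duration. On a
quasi-steady well-mixed population this recovers a constant kernel
exactly up to (n−1)/n (validated against a Gillespie oracle). On full
coarsening runs the absolute scale is biased — each size class is
populated for only part of the run, and the early-time Smoluchowski
transient inflates rates roughly 2× — so kernel *diagonals from
simulations are interpreted as trends* (flat for γ = 1 versus steeply
rising for γ = −2), while absolute-rate comparisons use the vanishing
calibration below.

**K(α) calibration.** In vanishing control runs all spheres have
volume 1 and merged pairs are reset to volume 1, so one sphere
effectively disappears per merger and the concentration obeys
dc/dt = −Kc²/2. Fitting 1/n(t) against t over the window where n has
decayed 20–80% gives K; at α = 1 and small Δr this matches the analytic
constant 4π(2D)(2R_ref) within the replicate CI (ratios 0.98–1.07
measured at Δr ∈ {0.1, 0.2}).

**χ.** For injection conditions, χ = τ_inject/τ_merge = ρ²K(α)/j with
ρ the *total injected* number density, j = J/V_sys, τ_merge = 1/(K(α)ρ)
and τ_inject = ρ/j. χ ≪ 1 predicts exponential distributions, χ ≫ 1
power-law-like ones; at very small χ almost nothing merges and the
distribution is just the injected monomer law (the "monomer-dominated
branch", flagged by the fraction of never-merged spheres).

## Statistics

Per cell (or replicate), the empirical CCDF = 1 − F is evaluated at the
sorted sample points (right-continuous). For cross-cell averaging each
cell's volumes are first divided by that cell's mean, the rescaled
CCDFs are interpolated onto a common geometric grid and averaged with
s.e.m. over cells; exponential populations then collapse onto exp(−v),
semi-log slope −1. Exponential fits regress ln CCDF on V over the
[5%, 95%] quantile window by default; power-law fits regress log CCDF
on log V (support under a decade triggers a warning). Both report 95%
CIs and an F test against the intercept-only model. The pdf exponent
is the CCDF exponent minus 1 (differentiation of the fitted tail; e.g.
CCDF exponent −0.41 ↔ pdf exponent −1.41).

Particle-weighted moments ⟨V⟩_p = ΣV²f/ΣVf and σ_p² = ⟨V²⟩_p − ⟨V⟩_p²
are used for growth curves; for an exponential law ⟨V⟩_p = 2μ and
σ_p² = ⟨V⟩_p²/2, so variance against mean has log–log slope 2. The
growth timescale ξ is the inverse slope of ln⟨V⟩ against time
normalized by the run duration. The coarsening collapse plots
(⟨V(t)⟩_p/⟨V(t₀)⟩_p)^(1/α) against t/t₀ with t₀ = 100; series
following ⟨V⟩_p ∝ t^α land on a log–log line of slope 1. A minimum
detection size v_min shifts the observed mean of an exponential
population by exactly v_min (memorylessness), and is corrected by
subtraction.

### Analysis windows (choices the data forced)

* Quench distribution shapes use (replicate, time) snapshots only after
  the mean volume has grown ≥ 3× (the uniform initial condition is
  forgotten) and while ≥ 15 spheres remain — rescaling by a small-sample
  mean systematically steepens the averaged CCDF.
* Collapse fits stop when the replicate-average alive count falls below
  5 (finite-size saturation: growth stalls once a couple of spheres
  remain). Per-α slopes are averaged with equal weight rather than
  pooled into one regression: the 1/α transform stretches small-α
  curves over several times more ordinate decades and would otherwise
  dominate the fit.
* Injection distributions pool the final state with snapshots over the
  last 70% of the run (every 7.5% of the duration): the cascade of
  sizes between the injection scale and the largest clusters is
  quasi-steady there, and single-instant populations at slow injection
  are too small (a handful of clusters) to resolve a slope. The log–log
  slope is fitted on a geometric grid spanning the full support, the
  same weighting a binned log–log curve gives.

## Study conditions and problem sizes

Full-scale presets follow the source conditions (quench: 1,000 spheres,
v_f = 5%, 10⁵ steps, 20 replicates; injection: 1,200 spheres to
v_f = 4%). The packaged studies run scaled presets chosen once:
quench 300 spheres × 10⁴ steps × 10 replicates per α; injection 400
spheres × 20 replicates with the box volume scaled by (400/1200)² so
that χ = N²K/(V_sys·J) is preserved exactly for the χ-matched
slow-injection condition (this raises the final volume fraction to
12%). The J sweep instead keeps the 4% volume-fraction geometry at
N = 400, because preserving χ per J cannot reproduce the fast-injection
(exponential) regime at reduced N — small-χ boxes land in the
monomer-dominated branch. Δr defaults to 0.5 in both modes (one of the
study's step sizes). With K(1) ≈ 3.7 at Δr = 0.5 the scaled χ values
are ≈ 1.2·10⁴ for J = 0.01 (χ-box) and ≈ 8 for J = 5 (4% box), placing
the two conditions on opposite sides of the exponential/power-law
divide.

## Known limitations

* At α < 2/3 the fBm explores space compactly and the mean grows
  closer to t^(3α/2) than t^α at these densities; the α = 0.25 collapse
  slope overshoots 1 by ~0.2–0.5 while α ≥ 0.5 agree within ~0.2.
* The regime boundary in J between exponential and power-law
  distributions depends on Δr through K; at Δr = 0.5 and N = 400 it
  sits near J ≈ 5 rather than J ≈ 0.1. The dimensionless statement —
  CV is a single increasing function of χ — is the invariant the tests
  check.
* The empirical kernel estimator's absolute scale is only meaningful on
  quasi-steady populations (see above).
* The synthetic stacks emulate bright voxelized spheres over Gaussian
  background at stated voxel sizes; they contain no PSF blur, no
  nuclear texture, no anisotropic optical distortion and no temporal
  dynamics. Tests passing on them certify the pipeline's logic
  (thresholding, connectivity, size filters, law recovery, detection-
  floor bias), not robustness to real microscopy artefacts.
* Sphericity is assumed throughout; 2D (projection) mode converts areas
  to volumes by V = (4/3)π(A/π)^(3/2).

## Degenerate inputs and numerical choices

Zero-variance images threshold at the mean (flagged); empty
segmentations return empty tables; a non-growing mean yields ξ = ∞;
single-sphere systems are valid fixed points of the dynamics; overlap
resolution at pathological volume fractions collapses to one sphere
with a warning. Circulant-embedding eigenvalues are clipped at zero
(round-off only). Positions live in [0, L) with explicit wrap of the
boundary value. All randomness flows from numpy `SeedSequence` spawns
of one master seed; equal seeds give bit-identical runs, including
across the two collision detectors.
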