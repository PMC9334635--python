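# Methods

This note documents the models implemented in `cavity_demix`, the
assumptions behind them, the numerical choices, and what the synthetic
generators do and do not emulate.

## Geometry

Cavities are ellipses centred at the origin with the major axis along +x,
lengths in micrometres. The family is parameterized by eccentricity `e`
and a reference radius `r0` (the radius of the `e = 0` circle) at fixed
etch depth `h` (default 0.2 µm): `A = r0 (1−e²)^(−1/4)`,
`B = r0 (1−e²)^(+1/4)`, so the in-plane area `πAB = πr0²` — and with `h`
constant, the volume — is invariant across the family. The boundary is
discretized uniformly in the parametric angle `t`, with the metric carried
by arc-length weights `ds = √(A²sin²t + B²cos²t) dt`; this keeps every
quantity closed-form (no arc-length root finding). The effective radial
coordinate `r_eff = √(x²/A² + y²/B²)` labels confocal elliptical contours
(0 at the centre, 1 on the wall).

## Mean-field chain concentration

A long chain in a shallow cavity is treated as a quasi-2D semi-dilute
solution under ground-state dominance: the monomer density is
`ρ(r) = (N_bp/h) ψ²(r)` with `ψ` the minimizer of

    E[ψ] = ∫ (a_k²/6)|∇ψ|² + (g/2)ψ⁴ dA,   ∫ψ² dA = 1,  ψ|∂Ω = 0,

equivalently the ground state of `−(a_k²/6)∇²ψ + gψ³ = λψ`. Here
`a_k = 0.1 µm` is the Kuhn length (2 × 50 nm persistence length); the T4
default is 166 kbp, 60 µm contour, hence 600 Kuhn segments. The slit
dimension is integrated out (area density / h), so `ρ` carries bp µm⁻³.

**Coupling g.** The self-interaction magnitude in these reduced units is
not experimentally pinned; only the profile *shape* propagates downstream
(the amplitude is absorbed into the fitted exclusion coefficient `a`). The
default `g = 0.05` keeps the weakly-interacting, centre-peaked regime
(centre density ≈ 2× the cavity mean for the `r0 = 1 µm` family). This is
a deliberate choice: in the strongly-interacting (flat, Thomas–Fermi)
regime the chain-exclusion potential `aρ` becomes nearly uniform and the
off-centre probability ring of the plasmid distribution — the phenomenon
the model exists to describe — disappears. Fits should always report the
`g` they used; `solve_gsd` records it in the field metadata.

**Numerics.** Regular Cartesian grid masked to the ellipse (default
spacing 25 nm, half the 50 nm comparison bin, and required ≤ B/10);
Laplacian with boundary-fitted Shortley–Weller stencils — stencil arms
crossing the wall are shortened to the exact intersection, where ψ = 0 —
giving second-order accuracy at the curved Dirichlet boundary (a plain
masked 5-point stencil has O(h) staircase error, an order of magnitude too
coarse for the solver's Bessel-oracle test). Imaginary-time propagation
with the diffusion term implicit (one sparse LU factorization reused every
step, unconditionally stable) and the cubic term explicit; ψ is clipped
non-negative and renormalized each step, the step adapts to `g·max ψ²`.
Initialization is the symmetric nodeless paraboloid
`ψ ∝ (1 − x²/A² − y²/B²)₊`; convergence is declared when the relative
per-iteration change of λ falls below 1e−10 (typically ~50 iterations).
λ is monotonically non-increasing along the iteration (energy descent),
which the tests assert.

## Plasmid potential and Boltzmann map

The plasmid feels `U_p(r) = a ρ(r) + U_wall(r)` in k_BT, with

* `a` (k_BT µm³ bp⁻¹) the linear exclusion coefficient; default
  `1.1e−6`, the magnitude recovered by fitting this model class to
  tracked plasmid data.
* `U_wall(r) = Σ_s u(|r_s − r|) Δs` the boundary integral of a short-range
  kernel over ≥ 180 (default 720) segments; distances go to segment
  midpoints, whose discretization error at 720 segments is below grid
  resolution for the exponential kernel (the much steeper WCA kernel is
  validated at 2880 segments).

Kernels: exponential `u(d) = b·exp(−d/r_b)` (default `b = 300 k_BT/µm`,
`r_b = 50 nm` — chosen so the integrated wall potential reaches 2 k_BT at
190 nm from the wall of the `r0 = 1 µm` circle, the experimentally quoted
interaction range; the kernel parameters themselves are not separately
identified by that one number), or the WCA (truncated–shifted
Lennard-Jones) form, cut at `2^(1/6)σ` and capped at 10³ k_BT µm⁻¹ as
`d → 0` (the cap only affects cells the plasmid never visits).

The equilibrium map is `P ∝ exp(−U_p)` normalized over interior cells
(shift-invariant by construction); `bin_to_resolution` block-sums
probability mass to the 50 nm observational pixel. The 2 k_BT range
diagnostic is measured inward along the minor axis (a convention; for a
circle every direction agrees, which the tests check against a closed-form
flat-wall inversion `U(d) = 2 b d K₁(d/r_b)`).

`effective_plasmid_radius` converts `a` to a hard-sphere radius through
the Flory identification `v = a × 300 bp`, `v = (4/3)πr_p³`. Note this
literal sphere reading yields ≈ 43 nm at `a = 1.1e−6` — an
order-of-magnitude estimate only, smaller than light-scattering coil
sizes; it is exposed as a diagnostic, not used anywhere downstream.

## Fitting

`fit_plasmid_model` maximizes the cosine similarity
`Σ p_i q_i / (‖p‖‖q‖)` between the observed and model maps at matched
50 nm binning. The objective is plateaued and has an exact additive-shift
degeneracy in `U`, so the search is derivative-free: a 5×5×5 log-spaced
seed grid over the bounds (`a ∈ [1e−8, 1e−4]`, `b ∈ [1e−2, 1e3]`,
`r_b ∈ [0.02, 1.0]`), then Nelder–Mead restarts from the best three seeds
in log-parameter space with a smooth quadratic out-of-bounds penalty (a
hard clip would hand the simplex gradient-free plateaus and strand it; the
penalty variant recovers `r_b` to < 1% on noiseless self-fits). The full
evaluation trace is recorded; the search is deterministic, so repeated
fits are bitwise identical. Uncertainty is reported as restart spread
only — no fit covariance is claimed.

Observed histograms must be built on the density solver's grid (pass the
density field as the histogram template) and then binned to 50 nm, so
model and data live on identical grids; empty bins are not smoothed.

## Brownian dynamics on landscapes

Euler–Maruyama, `Δr = −D∇F Δt + √(2DΔt) η`, with `∇F` from central
differences of the (exterior-filled) landscape, bilinearly interpolated at
the particle. Boundary handling is rejection-reflection: a step landing
outside the mask is retried with fresh noise (up to 50 times, then the
particle waits one step), which preserves detailed balance to O(Δt) —
long-run occupancy matches `exp(−F)` to total-variation < 0.05 at 10⁶
steps in the tests. Each clip consumes an independent child stream of the
run seed, so results are bitwise reproducible.

`D` and `Δt` are not constrained by the study being emulated: defaults are
`D = 0.5 µm² s⁻¹` (a ~100 nm particle in aqueous buffer) with
`√(2DΔt)` below the landscape grid spacing (enforced). Short-time MSD
exponents — the quantity compared across conditions — are insensitive to
`D` at matched lag ranges. For the plasmid-landscape simulations the
landscape is derived from the model `P` binned at 50 nm (the experimental
resolution), `Δt = 0.4 ms`, and 250 clips × 3000 steps (1.2 s clips) are
analyzed over the sub-second lag window; this reproduces strongly
anisotropic sub-diffusion (`α_∥ ≈ 0.88`, `α_⊥ ≈ 0.4` at `e = 0.9`) from
landscape structure alone. Positional hindrance by the chain solution
(microrheology) is deliberately *not* modelled, so minor-axis exponents
from these simulations under-count the anomaly seen in experiments — a
known, intentional limitation.

`F = −log P` uses a probability floor (default half the smallest positive
interior bin) so never-visited cells stay strongly repulsive but finite.

## Trajectory statistics

* **Tracking** — per-frame border-ring background estimation (median +
  3 MAD-σ noise floor, clamped at 0: without the noise floor the clamped
  positive shot-noise residuals form a pedestal that biases centroids
  toward the frame centre) followed by intensity-weighted centroiding.
  Frames untrackable in any channel are dropped consistently across
  channels. This background scheme is a simple documented substitute
  suited to the synthetic movies, not a reimplementation of any published
  noise-subtraction algorithm.
* **Order parameter** — the separation vector `r = r₁ − r₂` is a director;
  its stored angle θ is measured from the minor axis and folded to
  [0, π). The reported `S_align = 2⟨cos²φ − ½⟩` uses the angle φ to the
  *major* axis (φ = π/2 − θ), so perfect polar alignment gives +1 and
  isotropy 0, increasing monotonically through the demixing transition;
  the literal minor-axis convention (its negative) is available as an
  option.
* **Swap detection** — two-state assignment of the normalized major-axis
  projection with hysteresis: a state (±1) is entered beyond
  ±enter_threshold (default 0.5) and retained until the *opposite* enter
  threshold is crossed. Failed swap attempts — excursions crossing the
  opposite exit band (default 0.25) but not the enter band — are counted
  but do not terminate dwells. First and last intervals are censored and
  excluded from fits. The hysteresis rule is this package's explicit,
  testable debouncing choice.
* **Dwell fits** — single-exponential τ from a least-squares fit to the
  log empirical survival curve (R² and the sample mean reported;
  R² < 0.9 flags a poor fit); two-component mixtures by EM maximum
  likelihood with τ_long ≥ τ_short enforced and the nested
  single-exponential log-likelihood reported for comparison. Histogram
  least squares is intentionally avoided as binning-dependent.
* **Pole dwells** — a molecule is pole-resident when `|x| > l/3` with `l`
  the maximum major-axis extension (default: the trajectory's own
  max |x|); runs must be sign-consistent (direct pole-to-pole crossings
  split at the sign change) and edge-touching runs are censored.
* **MSD** — time-averaged per-axis curves; exponents by log-log linear
  regression over the short-time window (default up to 1 s) with standard
  errors from the regression.
* **Profiles** — mean probability density binned by radius (normalized by
  the semi-major axis) or by `r_eff`; empty bins stay NaN. The 1/e edge
  scans outward from the profile maximum with linear interpolation; edge
  shifts convert to µm via the cavity radius (radial mode) or the mean of
  the semi-axes (elliptical mode — the scale of one unit of `r_eff`).

## Synthetic data

The generators define the study conditions the tests run under:

* **Two-blob surrogate** — each chain is a point particle; mutual
  exclusion is a Gaussian-core potential
  `U_pair = A_p exp(−|r₁−r₂|²/2σ_p²)` and the wall acts through the same
  boundary-integral machinery as the plasmid model (force interpolated
  from a precomputed 50 nm grid). Defaults — `A_p = 7 k_BT`,
  `σ_p = 0.7 µm` (the λ-DNA coil scale), wall `(20 k_BT/µm, 80 nm)`,
  `D = 0.4 µm² s⁻¹`, `Δt = 2.5 ms`, 50 ms frames — were calibrated once
  to the qualitative organization the surrogate must reproduce: a
  centre-depleted (donut) centre-of-mass distribution at `e = 0`, polar
  alignment with `S_align > 0.5` at `e = 0.9`, and pole-swap dwells of
  order 10 s that grow with eccentricity. A point blob has no
  conformational degrees of freedom, so absolute barrier heights and
  dwell times are not quantitative chain predictions; the eccentricity
  *trends* are the meaningful output. Bead-spring chains are out of
  scope.
* **Boltzmann sampling** — rejection sampling against the cell-binned
  Boltzmann weight (uniform proposals over the bounding box), exact with
  respect to the binned density the fits compare against; an optional
  exact-ellipse rejection guarantees in-cavity samples. Aborts with
  advice if the acceptance rate falls below 1e−4.
* **Crowding** — emulated at parameter level: crowders at volume fraction
  v_φ scale the wall decay range by `(1 + 5 v_φ)` (crowders accumulate at
  the perimeter, extending the depletion zone) and the exclusion
  coefficient by `(1 + 5 v_φ)` (crowding compacts the chain, raising its
  local density). The coefficients are phenomenological, chosen to
  reproduce the observed direction and anisotropy-enhancement of the edge
  shift; no explicit crowder particles are simulated.
* **Movies** — integrated-Gaussian (erf) PSF blobs, uniform background,
  Poisson or Gaussian shot noise; 5000 photons/frame default keeps
  centroid noise (~7 nm RMS) far below the 50 nm bin. Frames with blob
  centres within 3σ of the frame edge are flagged as clipped.

All generators are bitwise deterministic under their seed (per-replica /
per-clip spawned streams).

## Problem sizes in the test suite

The validation suite runs at desk scale, chosen to keep every check
statistically decisive: Bessel-oracle solve at R/100 spacing; 10⁶ BD steps
for the Boltzmann-consistency check; 50,000 sampled positions for
parameter recovery; 16 replicas × 2–4 minutes of simulated time per
eccentricity for the phenomenology sweep (dwell-sample counts ≥ 20 even at
`e = 0.9`); 250 clips × 3000 steps for the MSD exponents; 500 / 2000
events for the dwell-fit recoveries. The scaled-down surrogate-vs-
Boltzmann marginal check (~10⁵ frames on 0.2 µm comparison bins) keeps
the same 0.05 total-variation bound as the full-size criterion.

## Known limitations

* Ground-state dominance with a scalar `g` ignores chain stiffness; for
  `e > 0.9` the cavity becomes tube-like and the concentration model is
  not trusted (fits there are out of scope).
* The point-blob surrogate has no internal conformations: barrier heights,
  and hence absolute swap times, are calibration-dependent.
* BD uses a constant, isotropic `D`; polymer-solution microrheology (the
  likely source of extra minor-axis sub-diffusion in experiments) is not
  modelled.
* Crowding is a parameter map, not a crowder simulation; `c1 = c2 = 5`
  are not fitted to data.
* The background-subtraction scheme targets the synthetic movies' uniform
  background; structured experimental backgrounds would need the imaging
  pipeline extended.
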