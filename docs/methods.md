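# Methods

## Observables and moments

All computations reduce to the first two raw moments (m1, m2) of the
distribution of donor fluorescence lifetimes sampled during a burst.  The
donor fluorescence intensity is proportional to m1 (each species emits in
proportion to its lifetime), so the intensity-based FRET efficiency is
E = 1 − m1/τ_D0.  The mean TCSPC delay time of an ideal (δ-excitation,
background-free) measurement is m2/m1 — the intensity-weighted average
lifetime τ_F, which in this regime coincides with the maximum-likelihood
single-lifetime estimate.  Because τ_F ≥ m1 with equality only for
zero-variance (single-lifetime) species, the pair (E, τ_F) carries the
variance of the underlying lifetime distribution:

    Var(τ) = m2 − m1² = (1 − E)(E − E_τ) τ_D0²,   E_τ = 1 − τ_F/τ_D0,
    Var(E) = Var(τ)/τ_D0².

The moment difference Γ = m1/τ_D0 − m2/τ_D0² = (1 − E)(1 − τ_F/τ_D0) is
linear in the moments; since kinetic mixing combines moments linearly in
the occupancy fractions, every mixing process is a straight line (two
states) or a simplex (n states) in the (E, Γ) plane, while single-lifetime
species form the parabola Γ = (1 − E)E with maximum (1/2, 1/4).

Every line generator in the package computes (m1, m2) as a function of one
swept parameter and maps them through these transforms; the generic engine
`line_from_lifetime_distribution` makes that recipe explicit and each
specialized generator is tested to agree with it.

## Line families

* **Static ideal** — δ-distributed lifetime, swept over E.
* **Dynamic (two-state)** — moments mix linearly in the occupancy x1;
  in (E, τ_F) the line is the hyperbola
  E = 1 − (1/τ_D0)·τ1τ2/(τ1 + τ2 − τ_F).  The **dynamic shift** is the
  maximal orthogonal distance to the static line in the normalized
  (τ_F/τ_D0, E) plane, ds = (1/√2)(√(1−E1) − √(1−E2))².  The prefactor was
  fixed by requiring agreement with brute-force distance maximization
  (`dynamic_shift_numeric`), which the test suite re-verifies on random
  efficiency pairs; the closed form and the optimizer agree to <1e-9.
* **Three-state** — pairwise dynamic lines bound the mixing triangle; the
  constrained lines varying one fraction with the other two equal meet at
  x = (1/3, 1/3, 1/3).  `fractions_from_position` inverts a population
  position by the segment-ratio construction (equivalently barycentric
  coordinates, which is how the tests cross-check it).  Out-of-triangle
  points raise and report signed coordinates rather than clamping, so
  callers can distinguish shot-noise excursions from model violation.
  More than three states are not invertible from a 2-D position.
* **Donor mixtures** — for multi-exponential donors, a donor state j with
  FRET rate k_i has lifetime τ_ij = 1/(1/τ_D0(j) + k_i) (homogeneous
  approximation: the joint distribution of donor states and FRET rates
  factorizes).  Quantum-yield weighting replaces E by the proximity ratio
  E_PR = 1 − ⟨τ_DA⟩/⟨τ′_D0⟩ with τ′_D0 = τ_DA + γ′(τ_D0 − τ_DA) and
  γ′ = Φ_A/Φ_D(j) per donor species.  Γ is then normalized by the
  intensity-weighted donor-only lifetime τ_D0F (recorded in the curve
  metadata); with that normalization Γ is negative wherever τ_F exceeds
  τ_D0F, which happens for donor species longer-lived than the mixture
  average.  Fast-exchange lines sweep a single FRET rate on a logarithmic
  grid spanning [1e-4, 1e4] × 1/τ_D0,max (plus k = 0 for the intercept),
  which covers E_PR ∈ (0, 1) smoothly; the acceptor is treated as a single
  state.
* **Distance distributions** — linker motion is assumed slow against the
  fluorescence decay but fast against the burst duration, so each state
  carries a stationary distance density p(R) and lifetime moments
  m_ν = ∫ τ(R)^ν p(R) dR with τ(R) = τ_D0/(1 + (R0/R)^6).  Families: the
  non-central χ (two isotropic Gaussian dye clouds — the physically
  preferred linker model), the truncated normal (common approximation;
  overweights short distances for broad widths), the Gaussian chain
  (Maxwell form, ⟨R²⟩ = 3σ²), and the worm-like chain.  A practical
  default linker width is σ_DA ≈ 6 Å (the value calibrated on rigid DNA
  rulers); it is always an explicit argument, never hard-coded.  Mixtures
  keep components unexpanded and combine moments linearly; re-quadrature
  of the summed density is used only as a test oracle.
* **WLC** — the mean-field interpolation for the radial end-to-end
  density, p(x) ∝ x²(1−x²)^(−9/2) exp(−3/(4κ(1−x²))) with x = R/L and
  stiffness κ = l_p/L, normalized numerically (the normalization constant
  is always computed, never assumed; it depends only on κ and is cached).
  Verified limits: κ = 10 gives mean R = 0.985 L (rod); κ = 0.05 gives
  ⟨R²⟩ within ~4% of the ideal-chain value 2κL².
* **Order–disorder** — linear moment mixing between a compact χ state and
  a WLC state over the folded fraction; straight in Γ although both
  endpoints are distance-broadened.

Variances decompose exactly as total = between-state variance of the
linker-averaged means + fraction-weighted mean of within-state linker
variances; `variance_decomposition` returns the three terms.

## Numerical choices

* Units are fixed: ns, Å, 1/ns (rates), 1/ms (kinetic rates in the
  simulator).  No conversions inside the numerics.
* Species fractions must sum to 1 within 1e-9; there is no silent
  renormalization — a violated sum raises, so caller bugs surface.
* E = 1 maps to τ = 0; divisions by τ_F guard with a 1e-12 ns epsilon and
  raise on a true zero first moment.
* Quadrature is adaptive (scipy `quad`, relative tolerance 1e-9) on
  [max(0, Rmp − 10σ), Rmp + 10σ] for χ/normal, [0, 12σ] for the Gaussian
  chain and [0, L] for the WLC; non-convergence raises with diagnostics.
  τ(R) floors R at 1e-3 Å to avoid overflow of (R0/R)^6; the density
  there is negligible for every supported family.
* The χ density switches between a cancellation-free sinh form (small
  R·Rmp/σ²) and the direct difference of normal densities (large
  argument, overflow-free).
* Default line sampling is 201 points, uniform in the curve's natural
  parameter; all generators accept the count.

## The burst simulator

The simulator produces the idealized experiment the line formalism
describes: a continuous-time Markov chain over the conformational states
(Gillespie dynamics, initial state from the stationary distribution),
homogeneous Poisson photon emission at a fixed per-molecule count rate
(default 100 photons/ms), Bernoulli donor/acceptor color splitting with
the instantaneous state's efficiency, and exponential donor TCSPC delays
with the state's quenched lifetime.  Burst durations default to an
exponential law with mean equal to the diffusion time (0.5 ms), truncated
at 10× the mean; a fixed-duration mode exists for clean estimator tests.
Bursts below `min_photons` (default 50) are rejected and counted.  One
root seed spawns an independent child RNG stream per candidate burst, so
burst k is bit-reproducible regardless of how many bursts are requested.

Deliberately absent: diffusion-path brightness variation (a burst has
constant rate), background, IRF convolution, acceptor delay times and
acceptor photophysics (blinking/bleaching).  Passing tests therefore
validate the estimator ↔ line relations under ideal photon statistics;
they do not establish robustness to background, crosstalk, correction
factors or acceptor dark states, all of which real data have.

## Estimators

Per burst: Ê = n_A/(n_A + n_D); τ̂_F = mean donor delay (bursts without
donor photons get NaN lifetimes and are excluded from lifetime histograms
with a logged count); BVA σ_E over consecutive non-overlapping windows of
N = 5 photons (trailing partial window discarded; an overlapping mode is
available as an option) against the binomial reference √(E(1−E)/N); and
the variance-from-observables (1 − Ê)(Ê − Ê_τ), which contains no
shot-noise term and, unlike BVA, does not decay for exchange faster than
the photon sampling.  As a product of two noisy estimates its expectation
is Var_c(E) − E(1−E)/n; the validation tests add the known binomial term
back before comparing binned means with the two-state parabola
(E − E1)(E2 − E).  The BVA-minus-shot-noise subtraction is provided but
documented as approximate (the contributions are not additive, and window
averaging biases it low); it degenerates at N = 1.

## Validation study sizes

The bundled validation runs use 2000 bursts for the two-state study
(E = 0.25/0.80, rates 1/ms, 0.5 ms mean bursts at 100 photons/ms) and
1200 bursts per rate for the rate sweep 0.1–100/ms, with Monte-Carlo
oracles of 10^6 samples — sizes at which the 3-SE checks have comfortable
resolving power while the whole suite runs in well under a minute of
simulation time.

## Known limitations

* The proximity-ratio machinery assumes a single acceptor state and
  ignores the α/β/δ correction-factor pipeline of quantitative FRET.
* Distance-dependent linker widths σ(R_mp) have no default model; the API
  takes per-state widths, which covers the published use cases.
* The WLC density is a mean-field interpolation; it reproduces the rod
  and ideal-chain limits but is not exact at intermediate stiffness.
* Lines are reference curves for graphical analysis; the package does not
  fit lines to burst histograms or extract rate constants.
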