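# Methods

`fracperm` models the one-dimensional motion of a small permeant along the
membrane normal z, from free-energy assembly through kinetic inference to
permeability. This note records the models, the numerical choices, and what
the synthetic benchmarks do and do not establish.

## Transport models

**Classical.** The Smoluchowski equation

    ∂c/∂t = ∂z [ D(z) ( ∂z c − β F(z) c ) ],     β = 1/(k_B T),

describes Markovian diffusion of the permeant concentration c(z, t) on an
inhomogeneous landscape: D(z) is the local diffusivity (Å²/ns) and
F(z) = −∂z w(z) the mean force from the PMF w(z) (kcal/mol). k_B =
0.0019872 kcal·mol⁻¹·K⁻¹ and the default temperature is 308 K, the
liquid-crystalline regime of a POPC bilayer.

**Fractional.** Permeants inside the bilayer are subdiffusive on 1 ps–1 ns
timescales (anticorrelated consecutive displacements, cusp-peaked
non-Gaussian propagators, MSD ∝ t^α with α < 1). The time-fractional
generalization replaces ∂/∂t by a Caputo derivative of position-dependent
order α(z) ∈ (0, 1] and D(z) by a fractional diffusivity K_α(z) with units
Å²/ns^α. α(z) ≈ 1 recovers classical diffusion in the aqueous phase; in
the bilayer core α drops to ~0.7. Because K_α's units depend on α, the
solubility–diffusion integral does not apply to the fractional model; only
the steady-state flux route does.

## Discretization

Space is a uniform grid (default ±45 Å, h = 0.5 Å; refined to h = 0.2 Å in
cross-checks). The spatial operator is a flux-conservative finite-volume
stencil with half-width wall cells. Half-node fluxes use midpoint values of
the fields' cubic interpolants (C¹-continuous; midpoint evaluation is a
cached linear map of node values) and the exponentially-fitted
Scharfetter–Gummel form

    J_{i+1/2} = (D_{i+1/2}/h) [B(−x) c_i − B(x) c_{i+1}],   x = βF_{i+1/2}h,
    B(x) = x/(e^x − 1),

which reduces to central differencing at F = 0, stays stable for steep
forces, and makes the Boltzmann density exp(−βw) discretely stationary.
Zero-flux (Robin) walls are implemented by setting the wall flux to zero in
the half cells, which conserves the trapezoidal mass to round-off; Dirichlet
boundaries pin the wall concentrations (driven-flux permeability).

Time stepping is Crank–Nicolson with τ = 500 fs by default. For zero-flux
classical problems the scheme obeys detailed balance, so the operator is
symmetrized exactly and diagonalized once (`eigh_tridiagonal`); repeated
stepping becomes a diagonal power and multi-lag propagators are nearly
free. This spectral path is algebraically identical to stepping (verified
to 1e−12) and is what makes desk-scale Bayesian sampling fast.

The fractional solver uses the L1 Caputo discretization (the scheme of the
finite-difference literature for time-fractional diffusion): at step m+1
the memory term Σ_{k=1..m} b_k (c^{m+1−k} − c^{m−k}) with
b_k = (k+1)^{1−α} − k^{1−α} is accumulated per node with that node's local
α, and the spatial operator is Crank–Nicolson-averaged. α ≡ 1 reduces
exactly to the classical step (all b_k = 0 for k ≥ 1). The memory sum makes
n steps cost O(n²); no truncation is applied. Because the L1 weights
assume uniform steps, a lag is reached with τ_eff = lag/⌈lag/τ⌉ rather
than by shrinking the final step (the classical propagator does shrink the
final step). How the force couples to the fractional operator is not
uniquely defined; here the memory acts on the time derivative and the full
drift-diffusion operator is averaged in the Crank–Nicolson sense, the
placement used by the L1/Crank–Nicolson literature.

## Propagator likelihood and Bayesian inference

A trajectory is split into non-overlapping displacements over a lag Δt.
The displacement probability is the propagator solution from a discrete
delta (density 1/cell-width at the start node) read off at the node nearest
the endpoint, times that node's cell width — so the discrete distribution
sums to one under zero-flux walls. Displacements sharing a start node share
one PDE solve; all start nodes are evolved as columns of one banded system.
The code works with the cost −ln P to avoid underflow.

The prior on each positive field is Jeffreys (1/value per node, scale
invariance) times a Gaussian penalty on the finite-difference gradient with
scale ε (default 50 Å/ns for D and K; 0.05 Å⁻¹ for α, which has a uniform
rather than Jeffreys base measure since it is bounded). This is the
simplest prior expressing the two assumptions it encodes — scale
invariance and weak smoothness of the parameter fields.

Sampling is Metropolis–Hastings with single-node updates: a field and node
chosen uniformly, the value shifted by s·T with T standard Cauchy
(symmetric long-tailed proposal, no Hastings correction; s = 2 Å²/ns for
diffusivity fields, 0.02 for α). Out-of-range proposals are rejected.
Every 10th state is stored and means are taken over the last 4/5 of stored
samples. The full-scale protocol attempts 10000 updates per node; the
package default is a desk-scale profile of 2000 per node on a reduced grid
(±20 Å, h = 1 Å, 41 nodes), which keeps a complete inference under two
minutes. Acceptance rates between roughly 0.6 and 0.9 are typical here; a
warning fires outside (0.01, 0.99).

Fractional inference is two-stage: stage 1 samples α(z) and K_α(z) jointly
against the pooled likelihood at two short lags (4 and 8 ps — short lags
disambiguate the order); stage 2 fixes a mirror-symmetrized, 5-node
moving-average-smoothed version of the stage-1 posterior-mean α(z) and
samples K_α(z) per lag. The (α, K) fields start from a method-of-moments
estimate (α from the displacement-variance ratio across the two lags, K by
moment matching) — an unbiased data-driven start that shortens the
convergence phase; the classical D field starts from the uniform 200 Å²/ns
convention.

At desk scale (10 ns of data, Δt = 8 ps, ≈1250 displacements) the per-node
posterior width for D(z) is ±15–25%: the posterior mean field tracks a
uniform truth to ~6–8% on average, but individual interior nodes can
deviate by ~20%. This is an information limit of that data volume, not a
sampler artifact (doubling the attempt budget does not change it), and is
why the recovery benchmarks assert field-level agreement and report the
per-node maximum.

## Permeability

Route 1 (classical): 1/P = ∫ exp(βw)/D dz by the trapezoid rule over the
membrane span, with w anchored at zero in bulk; Å/ns converts to cm/s by
×10. Route 2: Dirichlet driving c(−L/2) = c₀ + Δc, c(L/2) = c₀ (default
Δc/c₀ = 0.01, well inside linear response), evolve until steady. Steadiness
requires both a windowed relative change of the region-mean current below
1e−6 (window 1 ns) *and* z-flatness of the current below 1e−3 — the drift
test alone can trigger at a transient extremum. The current used is the
scheme's own half-node flux, which is exactly constant at the discrete
steady state; the node-centred centered-difference current remains
available for profile output. For fractional models the current is read
where α ≥ 0.95 (the effectively classical aqueous region) and the full
J(t) history is reported, since a time-fractional medium approaches its
driven steady state only asymptotically. Both boundaries must sit in bulk
(equal w); the net w-drop across the domain is reported as a diagnostic
because an unequal drop mixes an equilibrium flux into the driven one.
Route equivalence for classical transport holds to <0.5% on h = 0.125 Å
grids (each route carries its own O(h²) bias, so coarse grids show ~1%
apparent disagreement).

## Diagnostics

The free subdiffusive propagator W_α(x, t) = M_{α/2}(ξ)/(2√(K t^α)),
ξ = |x|/√(K t^α), is evaluated by the convergent M-Wright series
Σ (−ξ)^n / (n! Γ(1 − ν(n+1))) (ν = α/2, 200-term cap) below a ν-dependent
crossover (ξ = 6 for ν ≥ 0.4, 8 for ν ≥ 0.3, 10 below — as far out as
float64 cancellation allows), and beyond it by the stretched-exponential
asymptotic

    M_ν(ξ) ≈ a ξ^{(ν−1/2)/(1−ν)} exp(−b ξ^{1/(1−ν)}),
    b = (1−ν) ν^{ν/(1−ν)},

scaled by a first-order correction 1 + c ξ^{−1/(1−ν)} matched to the series
at the crossover, so the two branches join continuously (<1% mismatch) for
all α. A crossover placed at fixed ξ = 3√2 would leave a 3–4% jump at
α ≈ 0.5 because the leading asymptotic converges slowly there; the matched
ν-dependent rule replaces it. Verified tail accuracy against a
high-precision reference is ~1e−4 relative. The ML fit maximizes
Σ ln W_α(Δx_i, Δt) over (α, ln K) by bounded L-BFGS-B from several starts,
jointly in both parameters (an alternative would fix K by moment matching
and fit only α; joint optimization is the design choice here).

MSD uses overlapping windows; region conditioning keeps windows whose z is
inside the region at both endpoints by default (a whole-path switch
exists). The consecutive-displacement correlation C(z, Δt) is the
normalized product moment 〈Δ1Δ2〉/√(〈Δ1²〉〈Δ2²〉) binned by the final
position. Shapiro–Wilk is delegated to scipy. The apparent-diffusivity lag
scaling fits log〈D〉 vs log Δt; MSD = 2DΔt maps the slope γ to an implied
MSD exponent 1 + γ.

## Synthetic generators

The generators define the study conditions for every benchmark.

* **Brownian dynamics** integrates the Itô overdamped update
  z ← z + [βD F + D′]dt + √(2D dt)ξ with reflecting walls; the explicit
  D′ drift makes the stationary density exp(−βw) regardless of D(z),
  matching the Smoluchowski convention of the solvers. Default dt = 50 fs
  with 1 ps output sampling; drift and noise amplitudes come from fine
  lookup tables of the profiles' cubic splines (numba-compiled core).
* **fBm** uses exact-covariance circulant embedding of fractional Gaussian
  noise; H = 0.35 gives the anti-persistent surrogate with increment
  correlation 2^{2H−1} − 1 ≈ −0.188 and MSD ∝ t^{0.7}.
* **CTRW** draws Gaussian jumps at Pareto renewal times with survival
  (t/τ₀)^{−α} (exponential in the α → 1 limit). Its hydrodynamic limit is
  the time-fractional equation with K = σ_jump²/(2Γ(1−α)τ₀^α). Benchmarks
  use τ₀ = 0.05 ps so that 4–8 ps lags are ≥80 waiting times deep into the
  scaling regime — at lag/τ₀ ≲ 10 the zero-jump atom (probability
  (t/τ₀)^{−α}) biases fitted orders low. CTRW statistics age (weak
  ergodicity breaking): displacement ensembles for inference are built
  from fresh walkers measured from t = 0, never from one long path.
  Recovery benchmarks launch walkers from solver grid nodes with a jump
  scale giving ~3-cell displacements: the likelihood bins endpoints to
  nodes and reads the propagator amplitude at the node, and when
  displacements barely span one cell that approximation blurs the cusp
  and biases the fitted order high by ~0.1.
* **Stratified windows** tile the domain with overlapping windows (nominal
  geometry: nine ~15-Å windows over 90 Å overlapping by 5 Å; that nominal
  geometry is slightly over-determined, so window length is snapped up to
  a bin multiple and the last window clipped). Per-bin gradients are the
  true ∂w/∂z plus Gaussian noise of sd noise/√count; counts are Poisson.
* **Packings** are random sequential insertions of hard spheres under
  periodic minimum-image checks. A planted cavity excludes centers within
  cavity_radius + atom_radius + probe_margin and seals the exclusion
  surface with a shell of spheres so the detected void keeps the nominal
  radius; an unsealed boundary lets the void bulge ~2× in volume through
  inter-atom gaps. Detected planted volumes run ~15–20% above the nominal
  ball at 0.5 Å voxels with a 1.5 Å probe (documented tolerance 30%).

What the generators do not emulate: real bilayer structure (heads/tails,
water penetration), hydrodynamic coupling to lipids, multi-dimensional
permeant dynamics, and any microscopic mechanism of subdiffusion (fBm-like
anticorrelation and CTRW-like waiting times are alternative surrogates, not
claims about the physics). Passing benchmarks therefore establishes the
correctness of the numerics and the self-consistency of the inference, not
the fidelity of any particular membrane model.

## PMF assembly

Windows combine by the count-weighted gradient mean; for a symmetric
bilayer the gradient is antisymmetrized as
g_sym(z) = [n(z)g(z) − n(−z)g(−z)]/[n(z) + n(−z)] (exact node mirror on a
symmetric grid; linear interpolation otherwise, with antisymmetry then
holding only to interpolation error). Integration is trapezoidal; the
constant is fixed by zero mean over a bulk anchor interval (default
−45 ≤ z ≤ −43 Å). Interior single-bin count gaps are bridged by linear
interpolation and flagged; wider gaps are an error. The half-split
uncertainty takes per-bin force SE |g₁ − g₂|/2 from the two halves of the
sampling and accumulates independent bin variances outward from the
anchor, σ_w² = Σ (σ_g Δz)²; Monte-Carlo replication shows this tracks the
true assembly spread within a factor of 2.

## Known limitations

* The fractional solver's O(n²) memory cost makes long fractional
  steady-state runs expensive; desk-scale analyses use reduced grids, and
  no fast-convolution compression is attempted.
* Position-dependent α is handled by using the local node's α in that
  node's memory row — exact in the uniform-α and α ≡ 1 limits, an
  interpolation elsewhere.
* Desk-scale inference benchmarks (problem sizes above) trade posterior
  sharpness for runtime; full-scale runs need the 10000-per-node schedule
  and the ±45 Å, h = 0.5 Å grid.
* Only orthorhombic periodic cells are supported in void analysis; voids
  are per-configuration (no time-linking across frames).
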