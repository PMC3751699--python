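# Methods

## Model

The proteome is a pair of coupled linear populations: X proteins
(ecological, inactivatable) and Y proteins (essential, protected). With
origination f₀, inactivation kᵢ (X only), duplication k₂ (copies are X),
and transitions k_XY, k_YX, the totals N = X + Y and Y obey

    dN/dt = f₀ − (kᵢ − k₂) N + kᵢ Y
    dY/dt = k_XY N − (k_XY + k_YX) Y.

A protein's degree ξ evolves, for a protein born in the steady-state era,
as dξ/dτ = g + vξ with

    g = f₀ξ₀/N∞ + μ(N∞ − 1),
    v = Δε + k₂ − kᵢ(1 − κ) − r − μ,

collecting the degree-independent sources (newborn partners, the uniform
part of pair formation) and the per-link net growth (preference and
partner duplication minus partner inactivation, spontaneous loss, and the
μ already counted in g). Pushing the protein-age density through the
degree trajectory gives the sum-of-two-shifted-power-laws degree
distribution, and its first moment gives the parabolic link law. All of
this is closed-form arithmetic in `core_model`.

### Exact versus first-order steady state

The familiar steady-state expression N∞ = f₀/[(1−κ)(kᵢ−k₂)] drops a κ·k₂
cross term (class-Y duplicates feed class X). We use the exact fixed
point of the linear system, N∞ = f₀(k_XY+k_YX)/c with c the determinant
of the decay matrix, and define the turnover φ ≡ f₀/N∞ =
1/(a₁/γ₁ + a₂/γ₂). With this convention three identities hold to machine
precision simultaneously — N∞·φ = f₀, mass conservation
f₀∫dn/dτ dτ = N∞ = ∫dn/dξ dξ, and the equality of the closed-form link
law with the quadrature of ξ·dn/dξ — whereas with the first-order φ each
identity carries an O(κk₂/φ) ≈ 3·10⁻⁴ error in the fitted regime. The
difference is far below every fitted standard error; it matters only for
internal consistency checks.

## Fitting

Degree histograms use unit bins up to a threshold (default 20) and a few
logarithmically spaced tail bins (default 4), each normalized per unit
degree, with a tail bin's abscissa at the mean degree of its members; the
exact tail ranges are configurable because they are a presentation
convention, not part of the model.

Histogram fits minimize weighted least squares on log(count). The weight
of a bin is √(protein count in the bin): the variance of the log of a
Poisson count n is ≈ 1/n, so this makes the asymptotic (Wald) standard
errors calibrated — verified by a simulation experiment in the test
suite: ≥ 90% joint 3-SE coverage of all five parameters over 100 Poisson
replicates of the binned reference histogram. The covariance is reported
unscaled (no reduced-χ² rescaling), which is correct when the weights are
calibrated. Label switching between the two shifted-power-law components
is removed by parameterizing β₁ = β₂ + Δβ, Δβ ≥ 0, and β₂ > 1 is
enforced so both components carry finite protein mass; without that bound
a substantial fraction of noisy replicates collapses to a non-normalizable
β₂ ≈ 0.5 corner. Goodness is reported as the mean relative error on the
linear scale and the Pearson correlation of log-predictions versus
log-observations, the conventions used for judging such fits.

The link law is linear in (p₁, p₂), so `fit_links_model` solves the
normal equations exactly (unweighted OLS); repeated calls are bitwise
identical and the coefficients over the ten shipped species summaries
reproduce the reference values to five significant figures.

The comparator families — power law A·ξ^(−c), power law with exponential
cut-off A(ξ+c₁)^(−c₂)e^(−ξ/c₃), and double exponential — share the same
objective and reporting. On noise-free model data the ordering of mean
relative errors is strictly model < PL-EC < PL, because the comparators
cannot represent the two-component shifted power law exactly.

`sample_degrees` draws continuous degrees from the two-Lomax mixture and
rounds to the nearest integer (degree d ↔ ξ ∈ (d−½, d+½]), so a
histogram of draws aligns with the density evaluated at integer
abscissas; draws below ½ are non-interacting and redrawn. Identifiability
caveat: the slow component carries only ~5% of the protein mass at the
reference parameters, so its exponent β₂ is meaningfully identified only
for samples of a few thousand proteins; at n ≈ 1000 the global optimum
genuinely sits at the β₂ boundary.

## Rate estimation

`chi_square` computes the seven model observables from the eight free
rates (kᵢ, k₂, k_XY, k_YX, ξ₀, μ, Δε, r), eliminating f₀ through
f₀ = N∞·φ at fixed N∞ = 4135, and returns the standardized squared
deviation from the reference observables; percent standard errors are
interpreted as percent of the estimate, the only reading under which the
reference rates reproduce the published fit quality (χ² ≈ 0.137). An
infeasible rate set returns +∞ rather than raising, so any optimizer can
traverse the boundary. Feasibility means: non-negative rates, kᵢ > k₂,
two real negative eigenvalues, κ strictly inside (0,1), v > 0, and
β₂ > 2 (finite link integral).

The minimizer is a multi-start random walk in log parameter space:
multiplicative Gaussian proposals with relative width 0.2, annealed by
×0.95 every 250 proposals, greedy acceptance (a Metropolis temperature is
available but defaults to 0), 32 restarts of 4000 proposals from broad
log-uniform feasible starts. The walk reports the best rate set and the
mean and spread of the top 10, which is the honest summary because the
problem is under-determined: **all seven observables are exactly
invariant under a global rescaling of the eight rates** (the observables
are static, so the model's time unit cannot be identified from them).
Only dimensionless combinations — β₁, β₂, ξ_r, κ, φ/v, ξ₀ — are
recoverable, and the tests assert recovery of exactly those (within 5%
from a zero-noise reference; best χ² < 10⁻³).

## Deterministic simulation

The proteome and cohort systems are 2×2 linear ODEs and the single-node
degree equation is scalar linear, so `ode_sim` integrates them with an
adaptive Runge-Kutta scheme at rtol 10⁻¹⁰ and provides the closed forms
(eigen-decomposition / two-exponential / exponential trajectory)
alongside as independent oracles; the suite checks agreement to 10⁻⁶
everywhere. Time grids start at the initial time: the first grid point
carries the initial condition. A cohort of newborn proteins halves on the
fast timescale ln2/γ₁ ≈ 0.08 (the fast mode carries a₁ ≈ 0.98 of the
amplitude); the slow mode γ₂ governs only the small differentiated
remnant and the late approach of the whole proteome to its steady state.

## Stochastic simulation

`network_sim` realizes the model as an exact next-event (Gillespie)
simulation on a simple undirected graph. Channel rates are O(1) closed
forms in N, L and the class counts; every event re-derives them. Births
wire a new X node to Poisson(ξ₀) distinct uniform partners (most
newborns are isolated since ξ₀ < 1; isolated nodes count toward N but
not toward degree histograms). Duplication copies all parent links and
never links parent to copy. Partner-side link loss on inactivation is
emergent, not a separate channel.

Pair-link creation needs a microscopic rule the mean-field equation does
not prescribe. Each node carries weight wᵢ = μ(N−1−ξᵢ) + Δεξᵢ; link
events fire at rate Σwᵢ/2 and draw **both** endpoints proportionally to
their weights, the partner being redrawn among the initiator's
non-partners. Drawing both endpoints by weight preserves each node's
expected gain rate wᵢ to first order — a uniform partner (available as
`partner_mode="uniform"`) would halve the effective preferential slope
and qualitatively break the exponential age–degree relation — and
redrawing the partner keeps the aggregate link-creation rate at exactly
Σwᵢ/2, the model's own bookkeeping for dL/dt (discarding blocked
proposals instead was evaluated and loses ~25–30% of the aggregate flux
to duplication-induced clustering, collapsing L).

Event logs record enough per event (e.g. a newborn's partner list) that
replaying a log against the initial state reproduces the final graph
exactly; observable traces N(t), Y(t), L(t) are piecewise-constant
replays sampled on a grid.

### What the simulator validates, and what it cannot

The ensemble means of N(t) and Y(t) follow the mean-field ODEs exactly
(the counts are a linear birth–death process), and the tests confirm
3-SE agreement over 50 replicates of an N∞ ≈ 200 system. For links, the
mean-field prediction at finite time is the age-structured integral
L(t) = ½∫₀ᵗ ξ(τ)(dn/dτ)dτ; the asymptotic link law is its t → ∞ limit
and is verified analytically against quadrature, while the ensemble test
compares L(t_end) with L(t_end) — the like-for-like finite-time check —
because at N ≈ 200 the asymptote includes degree mass at ξ > N that a
finite simple graph cannot hold.

Beyond first order the microscopic process deviates from the mean-field
theory in ways no simple-graph realization can avoid, and at scaled-down
size these are measurable: (i) preferential attachment makes a node's
partners older and therefore far more often class Y than the global
fraction κ (a measured link-end Y-share of ~0.17 versus κ ≈ 0.021 at the
reference scale), so the theory's partner-inactivation loss kᵢ(1−κ)ξ
overestimates real losses and the simulated link count outgrows the
mean-field prediction at large N·t; (ii) duplicates are born with their
parent's degree rather than ξ₀; (iii) saturated hubs cannot absorb their
allocated preferential flux, which the partner redraw redirects to
unsaturated (mostly young) nodes. The net visible effect at N∞ ≈ 200 is
a young-age mean degree ~10–15% above the deterministic trajectory — a
~3σ systematic at 50 replicates, which the corresponding acceptance test
surfaces — while the age–degree relation remains qualitatively
exponential and the degree distribution keeps its two-component
shifted-power-law shape. The pooled-histogram test therefore runs at the
full reference scale (N∞ = 4135, 10 replicates pooled), where hub
saturation is mild and the fitted tail exponent β₂ lands within a few
percent of theory; at N ≈ 200 the degree range spans less than a decade
and the five-parameter refit is unidentifiable regardless of seed.

### Problem sizes used by the test suite

Ensemble checks use 50 replicates of an N∞ ≈ 200 system to t = 1 (the
proteome is 99.4% equilibrated and the largest mean-field degree ≈ 19
keeps the whole horizon inside the theory's ξ ≪ N regime) and 10
replicates at N∞ = 4135 to t = 3 for the pooled degree distribution;
the random-walk budget is 2×10⁵ evaluations. These sizes were chosen so
the statistical assertions above are sharp at the stated replicate
counts.

## Input handling

Edge lists are two-column text (configurable columns for PSI-MI-TAB-like
exports); identifiers are opaque case-sensitive strings. Normalization
drops self-interactions and collapses duplicate unordered pairs — the
convention of the curated exports the summaries came from — and reports
raw/self/duplicate/malformed counts. Histograms, summaries and
trajectories are headered TSV; fit and estimation results are JSON with
the configuration and seed embedded.

## Known limitations

* The theory is steady-state: proteins from before the steady-state era
  (deep pre-eukaryotic history) are outside the model, and time-varying
  rates are not supported.
* The binary essential/optional classification is a simplification of a
  continuous fitness spectrum.
* Absolute rates are reported in model-time units; the calibration of
  one unit to ~10⁹ years is a documentation constant, never computed
  with, and the observables cannot identify the time unit (see the
  scaling degeneracy above).
* The stochastic simulator is an O(events) pure-Python loop; it is
  comfortable to N ~ 10⁴ per replicate but not beyond.
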