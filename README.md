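# ppi-kinetics

Kinetic modelling of protein–protein interaction (PPI) network evolution:
a reusable implementation of a two-class birth–death–duplication model of
the proteome with preferential link gain, for researchers who want to fit
interactome summary statistics, recover evolutionary rate constants, and
simulate network evolution forward in time.

## The model

Proteins belong to two classes: **X** (needed only for ecological
adaptation, can be inactivated) and **Y** (essential for basic processes,
protected from loss). New X proteins originate at rate *f₀*, X proteins
are inactivated at *kᵢ*, classes exchange at *k_XY* and *k_YX*, and every
protein duplicates at *k₂* (copies are class X and inherit the parent's
interactions). A protein's node degree ξ (number of interaction partners)
changes through links to newborn proteins (a newborn brings ξ₀ links to
uniform partners), pairwise link creation at per-non-partner rate *μ* with
a rich-get-richer bonus *Δε* per existing link, partner duplication, and
loss through partner inactivation and spontaneous decay at per-link rate
*r*.

At the proteome steady state (fixed point of dN/dt = dY/dt = 0) the model
gives, in closed form:

* the essential fraction κ = k_XY/(k_XY + k_YX) and size N∞ = f₀/φ,
  with φ the per-protein turnover;
* a two-exponential protein-age density
  dn/dτ = f₀ (a₁ e^(−γ₁τ) + a₂ e^(−γ₂τ));
* exponential degree growth ξ(τ) = (ξ_r + ξ₀) e^(vτ) − ξ_r, so older
  proteins have more interactions;
* a node-degree distribution that is a **sum of two shifted power laws**

      dn/dξ = A₁ (1 + ξ/ξ_r)^(−β₁) + A₂ (1 + ξ/ξ_r)^(−β₂),
      βᵢ = γᵢ/v + 1;

* a **parabolic link law** L = p₁N + p₂N(N−1)/2 relating the total number
  of interactions to the number of interacting proteins across species.

The inverse problem — recovering the eight free rates from the seven
fitted observables (A₁, A₂, β₁, β₂, ξ_r, p₁, p₂) — is solved by
multi-start random-walk minimization of
χ² = Σⱼ ((computedⱼ − fittedⱼ)/SEⱼ)².

The package ships the reference inputs as plain-text fixtures: the
(N∞, L) summaries of ten species interactomes (BIND/DIP/COSIN exports),
the seven observables fitted to the *S. cerevisiae* interactome with
their percent standard errors, and the estimated kinetic rates. A
Gillespie-type stochastic graph simulator realizes the same rules at the
level of individual proteins and links and validates the mean-field
theory.

## Worked example

```python
>>> import ppi_kinetics as pk
>>> kp = pk.load_fitted_kinetics()          # reference rate estimates
>>> ss = pk.steady_state(kp)
>>> round(ss.kappa, 4)                      # essential-protein fraction
0.021
>>> sd = pk.spectral_decomposition(kp)
>>> round(1/sd.gamma1, 2), round(1/sd.gamma2, 2)
(0.12, 0.35)
>>> fit = pk.fit_links_model(pk.load_interactome_summaries())
>>> round(fit.params["p1"], 5), round(fit.params["p2"], 9)
(0.73526, 0.000552383)
>>> ref = pk.load_reference_observables()
>>> round(pk.chi_square(kp, ref, pk.YEAST_N_INF), 3)
0.137
```

About 2% of proteins are essential at steady state; the proteome relaxes
on timescales 0.12 and 0.35 model-time units (roughly 1.2·10⁸ and
3.5·10⁸ years if one unit is taken as 10⁹ years) while a single protein
gains links on the slower 1/v ≈ 0.45 scale. The link-law fit over ten
species gives the per-protein and per-pair link probabilities p₁ and p₂,
and the χ² ≈ 0.14 confirms that the shipped rates reproduce all seven
fitted observables well within their standard errors.

The same pipeline is scriptable from the shell:

```sh
$ ppi-kinetics verify                  # run the built-in checkpoints
[PASS] chi-square at best-fit rates ~ 0.14 (chi2=0.1366)
[PASS] characteristic times 0.12/0.35/0.45 ((0.12, 0.35, 0.45))
[PASS] essential fraction rounds to 0.02 (kappa=0.0210)
[PASS] link-law OLS p1/p2 match reference to 4 s.f. (p1=0.73526 p2=0.000552383)
[PASS] f0 from steady state within 0.5% of reference (f0=34376.8)
[PASS] mass conservation (age integral = N_inf) (integral=4135.004914)
[PASS] link law equals quadrature of the distribution (L=7769.58)
[PASS] ODE integration matches closed form to 1e-6 (max rel dev=2.41e-11)
all 8 checkpoints passed
```

Other subcommands: `histogram` (edge list → degree histogram TSV),
`fit-degrees` (histogram → model/PL/PL-EC/2E fits), `fit-links`,
`estimate-kinetics` (random-walk χ² search), `simulate-ode`,
`simulate-network`. All stochastic commands take an explicit `--seed`
and embed it in their outputs.

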