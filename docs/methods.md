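# Methods

## Model class and assumptions

The package handles reaction networks of mass-action (or, for
coarse-grained models, user-supplied macroscopic) rate laws in a well-mixed
compartment of volume `Ω`, with concentrations as the primary unit and copy
numbers derived as `n = Ω·[X]` (rounded only when initialising stochastic
states). Three assumptions underpin every analytic result:

1. **Monostability** — a unique stable steady state of the rate equations;
   the Lyapunov solver refuses non-Hurwitz Jacobians.
2. **Small intrinsic noise** — molecule numbers large enough for the linear
   noise approximation (leading order of the system-size expansion) to hold.
3. **Timescale separation** — user-declared slow/fast species partition,
   valid in the same regime as the deterministic QSSA. The package does not
   auto-detect the partition; it provides a diagnostic
   (`timescale_separation_check`) that integrates the full and reduced rate
   equations and reports the maximum relative slow-species deviation
   (default pass threshold 0.05, a package default rather than a derived
   quantity).

Propensities follow `a_j = Ω f̂_j(n/Ω)` for elementary and heuristic laws
alike. Homodimeric steps therefore use `k n²/Ω`, not the combinatorial
`k n(n−1)/Ω`; none of the worked systems contains one, the difference is
O(1/Ω) (within LNA accuracy), and construction of such a network emits a
warning.

## The reduction pipeline

Rate laws are stored as sympy expressions (mass-action laws generated from
the stoichiometry), so the rate Jacobian `∂f_j/∂X_i` is exact — this is
what lets the closed-form cross-checks pass at 1e-8 relative rather than
finite-difference accuracy. Conservation laws are validated against the
left null space of `S` in integer arithmetic; one species per law (the
last-declared, unless named) is removed from the explicit state and
reconstructed symbolically inside every rate evaluation. A singular fast
Jacobian block is diagnosed as an uneliminated conservation law.

Steady states are found by ODE relaxation (LSODA, horizon doubling until
`‖S f‖/‖X‖ < 1e-8`) followed by Newton polishing (scipy `hybr`, then damped
Newton with backtracking) to relative residual ≤ 1e-10; stability is
re-asserted post hoc from the Jacobian spectrum with a margin of
`1e-12·‖J‖` against spurious marginal modes.

The three flavors share the Lyapunov/spectrum machinery and differ only in
`(J, D)`:

* full LNA: `J_F`, `D_F = Ω⁻¹ S diag(f) Sᵀ`;
* ssLNA: `J = J_s − J_sf J_f⁻¹ J_fs`, `D_ss = Ω⁻¹ S′ diag(f) S′ᵀ` with
  `S′ = S_s − J_sf J_f⁻¹ S_f`;
* hLNA: reduced-model `J` and `D_h = Ω⁻¹ S_cg diag(f_cg) S_cgᵀ`.

The noise prefactor in the reduced Langevin equation is implemented as
`Ω^(-1/2) S′ diag(√f)`, the unique square-root convention that makes
`D_ss = Ω⁻¹ S′ diag(f) S′ᵀ` and reproduces the worked closed forms
term-by-term; the enzyme and gene closed-form regression tests pin this
choice down.

Numerical choices: Lyapunov equations are solved by the dense
Bartels–Stewart routine (`scipy.linalg.solve_continuous_lyapunov`) with
iterative refinement until the residual is ≤ 1e-10·‖D‖ — refinement is
needed because the worked systems are stiff (decay rates spanning up to
seven decades); a Kronecker-vectorisation solve serves as an independent
oracle in the tests. Spectrum–variance consistency integrals are evaluated
by piecewise quadrature with decade-resolved panels for the same stiffness
reason.

## Oscillation diagnostics

A noise-induced oscillation is an interior maximum of `P_j(ω)` at
`ω* > 0`. The numeric rule accepts a peak when the refined interior maximum
exceeds `P_j(0)` by a relative prominence of 1e-6 (configurable); a
single-slow-species spectrum is a monotone Lorentzian-type curve and never
peaks. For two-species systems with diagonal diffusion the closed-form sign
criterion `(J₂₂²D₁ + J₁₂²D₂)(Tr²J − 2DetJ) − D₁Det²J < 0` is evaluated as
well and the two routes are required to agree (they are equivalent
analytically: the spectrum is a ratio of a linear to a quadratic polynomial
in ω², so a positive slope at ω = 0 is necessary and sufficient for a
unique interior maximum).

The gene-circuit bifurcation scan classifies each `(k0, ks)` cell from the
exact scalar steady-state balance, the *full-network* Jacobian for
stability and the closed-form peak criteria for both flavors. Stability is
judged on the full 5-variable Jacobian deliberately: the reduced
two-variable model is unconditionally stable (negative trace, positive
determinant), and the region without a stable steady state appears only
through the full circuit's deterministic (Hopf-type) instability at strong
drive. Scan ranges (`k0 ∈ [1e-2, 1e4]`, `ks ∈ [1e-3, 1e3]`, log-spaced,
default 60×60) were chosen so that all four regimes — no stable steady
state, no peak, both flavors peak, slow-scale-only peak — are present; the
representative points (316, 1e-3), (1, 10) and (0.01, 0.01) sit well inside
the last three regions and are cross-checked by numeric spectra and, for
the oscillatory point, by the periodogram of an exact simulation.

## Stochastic simulation

`ssa_simulate` is the Gillespie direct method: exponential waiting times
`τ = −ln(r)/Σa_j`, next reaction with probability `a_j/Σa`, states recorded
on a uniform grid by piecewise-constant interpolation (so periodograms and
block statistics are well defined; grid spacing configurable). Mass-action
networks run in a numba kernel (~1e7 events/s); custom-law networks use a
Python loop, acceptable because coarse-grained event rates are low.
Identical seeds give bitwise-identical trajectories.

`langevin_sslna` integrates the reduced Langevin equation by
Euler–Maruyama (default `δt = 0.1`, the step used for the worked sample
paths), warning when `ρ(I + Jδt) ≥ 1`. The Euler scheme's O(δt) variance
bias is visible and tested: halving-by-ten the step shrinks the error.

`trajectory_statistics` discards a 20% burn-in and reports means and
variances with standard errors from 20 contiguous blocks (declared
defaults). Block variances are centred on the global mean so that their
average equals the full-sample variance and the block spread is a
consistent error bar for it; with strongly autocorrelated slow modes the
block error bar is still mildly optimistic (blocks span ~10 correlation
times in the shipped checks), which is why the cross-check tests use fixed
seeds and 3-SE bands. The periodogram convention
`P̂(ω) = |Σ η e^{−iωt}Δt|²/T` makes its expectation match the analytic
two-sided spectra directly.

## Worked systems and chosen problem sizes

* **Enzyme** (7 reactions; S slow; EE, EES, SEES fast; EE eliminated).
  Closed forms for the reduction weights `q1, q2`, both variances, and the
  Michaelis–Menten (`k2 → 0`) and Hill (`k2 → ∞`, fixed `Km² = Km1·Km2`)
  limits. Headline parameters `EET = 1`, `k2 = 1000`, `k−1 = k−2 = 100`,
  `k3 = k4 = 1`, `Ω = 100`, with `k1 ∈ {5e-3, 5e-5, 5e-7}` and the input
  flux set through the saturation fraction `Θ = k_in/(k4·EET)`. Simulation
  cross-checks run at `k1 = 5e-3` (the cheapest of the three studied
  binding constants) for 8e3–4e4 time units.
* **Gene circuit** (11 reactions; M, P slow; GP, GP2, EP fast; G, E
  eliminated). Finite-parameter reduction weights
  `p1 = (k0/k1)[P]/(K² + K₂[P] + [P]²)`,
  `p2 = (k0/k2)(K₁+[P])/(K² + K₂[P] + [P]²)`, `q = ([P]+K₃)/([P]+K_M)`;
  the cooperative limit (`k2 → ∞`, `k1 → 0`, fixed `k1k2`) sets `p2 = 0`
  and the active gene fraction to `K²/(K²+[P]²)`. The reduced model is
  parameterised directly with `K` while
  simulations always use the finite-constant full network.
* **Two-stage expression** (4 reactions; P slow, M fast): `S′ = (b, −b, 1,
  −1)` and stationary protein variance `[P](1+b)/Ω` exactly; the
  block-diagonal variant that discards fast-reaction noise returns `[P]/Ω`,
  correct only for `b ≪ 1`.

## What the synthetic conditions do and do not show

All inputs are the printed parameter sets of the worked studies (or random
draws around them); there are no external data. Passing tests therefore
demonstrate internal consistency (generic machinery ≡ independent closed
forms; analytic ≡ numeric peak rules; SSA/Langevin ≡ Lyapunov covariances
in the LNA regime) and reproduction of the studies' quantitative claims —
they do not validate the chemistry of any real pathway, rate-law inference
from data, or behaviour outside monostable, timescale-separated regimes.

## Known limitations

* The LNA premise fails quantitatively when a discrete unit (here: a single
  gene copy) toggles on a timescale comparable to the slow relaxation. At
  the strong-repression point (`k0 = 100`, `Ω = 100`, one gene) exact
  simulation puts the mRNA variance far below the Gaussian prediction
  (relative fluctuations ~3) and shifts the protein mean by ~25%, while the
  protein Fano factor still agrees with the slow-scale value within a
  factor two — three orders of magnitude above the heuristic prediction.
  The strict 3-SE simulation checks therefore run at moderate drive
  (`k0 = 10`), with the strong-repression agreement asserted at the
  factor-two level. Finite-volume corrections beyond the LNA are out of
  scope.
* Bistable or absorbing-state systems, time-dependent rate constants,
  transient (non-stationary) covariances and spectra, spatial compartments
  and SBML import are out of scope.
* The timescale-separation criterion is operationalised through
  rate-equation trajectory agreement, not through estimated correlation
  times of fluctuations.
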