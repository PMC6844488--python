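# Methods

This note records the model, the inference procedures, the numerical
choices behind them, and what the synthetic tests do and do not
establish.

## Population model

Two compartments: stem cells S and non-stem daughter cells D. Cell-cycle
events occur at per-capita rates λ₁ (S) and λ₂ (D); deaths at γ₁, γ₂.
An S event realizes one of four scenarios with probabilities
p₁ (S→S+D), p₂ (S→D+D), p₃ (S→S+S), p₄ (S→D); a D event one of two,
q₁ (D→D+D) or q₂ (D→S+D). The scenarios D→S+S and D→S are excluded
(their probabilities set to zero): the single dedifferentiation channel
D→S+D already discriminates the regular mode from the one requiring a
genetic-program switch. Probabilities satisfy Σpᵢ = 1, q₁+q₂ = 1 and
0 ≤ pᵢ, qⱼ ≤ 1.

Bookkeeping of expected offspring gives a linear system

    dS/dt = α_S S + β_D D,    dD/dt = β_S S + α_D D,
    α_S = (p₁+2p₃−1)λ₁ − γ₁,   β_D = q₂λ₂,
    β_S = (p₁+2p₂+p₄)λ₁,       α_D = q₁λ₂ − γ₂.

β_S is a pure per-stem-cell rate; an S-factor sometimes attached to it
in informal writing is dimensional bookkeeping, not a nonlinearity —
only with the pure coefficient do the two displayed forms of the system
coincide. The stem fraction s = S/(S+D) follows the scalar Riccati
equation

    ṡ = c₀ + c₁s + c₂s²,
    c₀ = q₂λ₂,
    c₁ = (p₃−p₂−p₄)λ₁ − (1+q₂)λ₂ + γ₂−γ₁,
    c₂ = λ₂ − (1−p₄)λ₁ − γ₂+γ₁,

which is the bridge between population data (s(t)) and scenario
probabilities. Abundances are continuous and scale-free: only s(t)
matters downstream, so S₀ is arbitrary (default 1). Time units are
arbitrary; defaults are phrased in days to match the ~10-day
stabilization window of cultured lines, and rates default to λ₁=1,
λ₂=5 (stem divisions measurably slower), γ=0.1 (a measured 10%/day
death rate; 0.5 explores a near-critical alternative).

Forward simulation uses the classic fixed-step 4th-order Runge–Kutta
scheme; for constant probabilities the solution is also available in
closed form (2×2 eigen-decomposition), which the simulated-provenance
curves use for exact continuous-time evaluation. Steady-state fractions
are the roots of the Riccati balance in [0,1]; when all three
coefficients vanish (S and D grow identically) the sentinel
`ANY_FRACTION` is returned rather than the whole interval.

## Corridor inversion

Given s(t), ṡ(t) and the rates, the Riccati relation plus the two
simplex identities leave three free probabilities, parametrized as
(p₁, p₂, q₂); the closure

    p₃ = [ṡ − λ₂q₂ + (γ₁−γ₂+λ₁+λ₂ − λ₁p₁ + λ₂q₂
          + (γ₂−γ₁−λ₂+λ₁(p₁+p₂))s) s] / [λ₁ s (2−s)],
    p₄ = 1 − p₁ − p₂ − p₃,    q₁ = 1 − q₂

restores the rest. It is singular at s = 0 (and s = 2, outside the
domain); s = 1 is regular, so a pure-CSC start is legal.

The remaining freedom is resolved by the minimal-change principle:
at each instant the six probability derivatives minimize
Σᵢṗᵢ² + Σⱼq̇ⱼ² subject to the time-differentiated Riccati constraint
and the differentiated simplex identities. Biologically, each scenario
is implemented by dedicated molecular machinery, so trajectories that
re-program cells gratuitously are implausible. The resulting explicit
ODE system for (ṗ₁, ṗ₂, q̇₂) is equivalent to the minimum-norm solution
of that constrained least-squares problem — the test suite checks the
closed-form right-hand sides against an independent KKT solve at random
states to 1e-10.

**Integration.** An implicit midpoint scheme: the right-hand sides are
evaluated at half-step curve values and at the average of the current
and next free state. The numerator is *linear* in the unknowns, so the
update is a rank-one linear solve per step (Sherman–Morrison), exact
rather than fixed-point iterated. p₃ comes from the closure at the new
node, p₄ and q₁ from the conservation laws, so Σp = 1 and Σq = 1 hold
to machine precision at every step by construction. Global error is
O(Δt²) (Richardson ratio ≈ 4 under step halving). Half-step curve
values come from the curve's analytic form when it has one, otherwise
from its cubic spline.

**Sweep.** Initial triples (p₁₀, p₂₀, q₂₀) are swept over the unit cube
on a lattice (default step 0.05, i.e. 9261 triples; step 0.01 as in the
original procedure is available but ~100× slower). A triple is
discarded the moment any of the six probabilities leaves [0,1], with a
slack of 1e-9 absorbing roundoff at the boundaries. Trajectories of all
live triples advance simultaneously (the per-step linear map is shared,
so the sweep is vectorized); envelopes are the pointwise min/max over
whole-period survivors, computed in a second pass so early casualties
never contaminate them. Corridor boundaries are envelope curves — they
are generally composed of arcs of different member trajectories and are
not themselves solutions. Extremal unique solutions pick the surviving
triple extremizing one component (ties broken lexicographically
ascending), e.g. q₂₀→min for the least-dedifferentiation history.

A structural consequence worth knowing: at t=0 with s(0)=1 the closure
forces p₁(0) ≤ −ṡ(0)/λ₁. The maximal admissible asymmetric-division
probability therefore scales directly with the initial slope of the
stem-fraction curve, and any reported p₁ ceiling is curve-specific.

## Synthetic curves and derivatives

The default stabilization stand-in is the exponential relaxation
s(t) = s_eq + (s₀−s_eq)e^{−kt} (defaults s₀=1, s_eq=0.1, k=1 per day,
T=10, 201 points), chosen as the simplest monotone decay matching the
verbal description of the phenomenon; overshooting curves can be
produced through the simulated provenance instead. Parametric and
simulated curves carry analytic derivatives. Measured curves get s, ṡ,
s̈ from a cubic smoothing spline (penalty chosen by generalized
cross-validation when not given) because the inversion needs s̈, which
raw finite differences amplify catastrophically under sampling noise;
with zero smoothing a not-a-knot interpolating spline is used, exact
for polynomial data up to degree 3. Derivative estimates are least
reliable near the grid ends (spline boundary effects) — the noise test
asserts accuracy over the middle 80% only.

Closed-loop fixtures (`make_ground_truth_bundle`) forward-simulate
constant probabilities and attach the exact Riccati derivatives, so an
inversion starting from the true triple must reproduce the constants;
it does so to machine precision because constant states are exact fixed
points of the discrete scheme.

## Factor decomposition

The six recovered trajectories y_i(t) are modelled as
y_i(t_n) = Σ_k b_ik exp(−a_k(t_n−c_k)^m): K shared bump kinetics with
channel-specific amplitudes. m is fixed at 6 by default (steep
shoulders, near-trapezoid tops — a generic secreted-pulse shape) but
exposed as any even integer ≥ 2. The reported height b_k = maxᵢ|b_ik|
proxies the factor's peak concentration; fit quality is
ε = 100·Σ|y−ŷ|/(6N), in percent of the unit probability scale.

The quadratic objective is minimized by relaxing its stationarity
system in pseudo-time. Numerical choices:

- **Initialization** (the original procedure leaves it open): centers at
  the K most prominent peaks of Σᵢ|y_i(t)| with widths from the
  measured FWHM (exp(−a x^m) = ½ at x = (ln2/a)^{1/m}), equidistant
  fill-ins when fewer peaks exist; amplitudes from per-channel linear
  least squares. Deterministic, so the default path is seed-free.
- **Updates**: sequential blocks (widths, centers, amplitudes) with
  per-block adaptive steps — grow 1.3× on acceptance, halve on
  rejection — replacing hand-tuned pseudo-time steps; the objective is
  monotonically non-increasing by construction. Widths move in log
  space: a spans orders of magnitude and its gradient scales
  oppositely, while positivity and the stationary points are unchanged.
  By default amplitudes are solved exactly each iteration (variable
  projection), zeroing their residuals.
- **Escapes**: equispaced-or-peak starts can still strand a bump where
  the objective is flat (bump tails are super-exponentially small). A
  deterministic refinement relocates the weakest factor to the largest
  remaining residual and re-relaxes, kept only on improvement, at most
  K times. Seeded random restarts are available (`n_restarts`) but off
  by default.
- Exponents below −745 underflow to exactly 0 (guarded); widths are
  floored at 1e-10; convergence is declared when every stationarity
  residual falls below `tol` (default 1e-6).

K is selected by the smallest count ≥ K_start whose ε beats ε_p
(default 1%); after acceptance, factors with b_k < 0.01 (1% of the
probability scale — the threshold is a package choice, the original
rule states none) are pruned and the reduced set refit, so an oversized
start collapses to the essential factor count. The decomposition is not
unique in general; the spread of near-optimal solutions across restarts
is a diagnostic, not an assertion.

## Attribution

Factor k produced by stem cells should scale with s(t); by non-stem
cells, with d(t) = 1−s(t); by neither (or the environment), with 1.
Each of the 3^K label assignments multiplies the basis accordingly and
the whole parameter set is *refit* warm-started from the unmodulated
optimum (the cheaper amplitude-only screening is available behind
`refit=False`). Variants are ranked by ε; the all-1 variant always
appears and matches the unmodulated fit. When s(t) ≈ d(t) the S and D
labels are not identifiable — swap-tied variants (|Δε| < 1e-4
percentage points) are flagged rather than silently ordered.

## What the synthetic tests establish — and what they don't

Green tests establish internal consistency: the closure is algebraically
exact, the minimal-change flow equals its variational definition, the
scheme is second order and simplex-exact, forward-simulated ground truth
is recovered through the full corridor machinery, and factor/attribution
fixtures built inside the model family are identified correctly. They do
not establish that real FACS time series satisfy the model: measured
curves carry sampling noise (only mildly emulated), possible
non-monotonicity, and rate constancy is an assumption over the
stabilization window. The bump family is one basis choice; data
generated outside it will be approximated, not represented.

## Known limitations

- The sweep resolution bounds corridors from inside: a triple admissible
  at step 0.01 may be missed at 0.05, so envelopes at the default are
  slightly conservative.
- The closure is singular at s = 0; curves that hit a zero stem fraction
  cannot be inverted past that point.
- Attribution refits inherit the non-convexity of the decomposition;
  warm starts make the 3^K enumeration tractable but a globally better
  fit for some variant cannot be ruled out.
- Death and division rates are constants; time-varying rates are out of
  scope by design.
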