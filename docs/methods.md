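# Methods

## Model

`pnpiv` analyzes steady-state electrodiffusion of two oppositely charged ion
species (valences `z1 > 0 > z2`, constant diffusion coefficients `D1`, `D2`)
through a narrow channel treated as a quasi-one-dimensional pore on the
normalized axis `x ∈ [0, 1]` with cross-section area `h(x)`. The governing
equations are the dimensionless steady-state Poisson–Nernst–Planck (PNP)
system

```
eps^2 / h * d/dx ( h dphi/dx ) = -(z1 c1 + z2 c2 + Q(x)),
h ck' + zk h ck phi'           = -Jk,      Jk' = 0,      k = 1, 2,
```

with Dirichlet data `phi(0) = V`, `phi(1) = 0`, `ck(0) = Lk`, `ck(1) = Rk`.
Potentials are in units of kT/e, concentrations in units of a characteristic
number density, and `eps` is the (Debye-length-like) dielectric scaling
parameter. The permanent charge is piecewise constant: `Q = Q0` on a window
`(a, b)` (the channel neck), zero elsewhere. Only the ideal component of the
electrochemical potential is modeled — no ion-size (steric) corrections.

Two derived geometric quantities carry all the shape dependence: the
resistance integral `H(x) = ∫_0^x ds/h(s)` and the normalized window
positions `alpha = H(a)/H(1)`, `beta = H(b)/H(1)`.

The departure of the reservoirs from electroneutrality is encoded by

```
sigma = -z2 L2 / (z1 L1),      rho = -z2 R2 / (z1 R1),
```

with `sigma = rho = 1` the exactly neutral case (no boundary layers). The
current is `I = z1 D1 J1 + z2 D2 J2`, positive when net positive charge
flows from `x = 0` to `x = 1`.

## Analytic theory (eps → 0, small Q0)

The library implements the regular perturbation expansion of the current in
the permanent-charge amplitude,

```
I(V; Q0) = I0(V) + I1(V) Q0 + o(Q0),
I0(V) = P00 + P01 V                       (linear),
I1(V) = P10 + P11 V + P12 V^2             (quadratic),
```

with the five P-coefficients given in closed form as functions of
`(sigma, rho)` through

```
theta = z1/(z1-z2) (ln sigma - ln rho) + ln(L1/R1),
omega(x) = (1-x) sigma^q L1 + x rho^q R1,   q = z1/(z1-z2),
```

and the flux functionals `lam`, `A`, `B` (`iv.py`). The same current is
assembled independently from the per-species fluxes `J10, J20, J11, J21`
computed through the electroneutral boundary limits (`flux.py`); the two
code paths agree to ~1e-15 relative and this dual-path identity is the
primary correctness oracle of the test suite — it is asserted over randomized
valences `z1 ∈ {1,2,3}`, `z2 ∈ {-1,-2}`, diffusivities, concentrations,
relaxation factors `sigma, rho ∈ [0.5, 2]` and geometries.

A note on one formula choice: the right-hand boundary-layer potential is
taken as `phiR = -ln(-z2 R2/(z1 R1))/(z1 - z2)`, the mirror image of the
left one. This is required for the two assembly paths above to coincide and
for `theta` to equal `ln c1L - ln c1R`.

### Expansion about electroneutrality

Expanding each P-coefficient to first order in `(sigma - 1, rho - 1)` gives
the linearized relations and, by subtraction, the boundary-layer difference
terms `I0d` (linear in V) and `I1d` (quadratic in V) whose signs quantify
when layers enhance or reduce the current (`expansion.py`). All ten partial
derivatives are implemented in closed form and validated at build/test time
against central finite differences of the exact coefficients (step `1e-6`,
relative tolerance `1e-5`); a mismatch raises a formula-integrity error
rather than propagating a wrong derivative into the sign analysis. The
Taylor truncation error is second order: halving the relaxation distance
quarters the linearization error (asserted at `V ∈ {-2, 0, 2}`).

### Sign analysis and critical potentials

`sign_analysis.py` implements the threshold apparatus that organizes the
signs of `I0d` and `I1d` for `t = L1/R1 > 1` and `sigma > rho`:

- the shape function `ell(t) = (sigma-1) t ln t + (1-rho) ln t +
  (rho-sigma)(t-1)` whose sign is the sign of the slope of `I0d`; in the
  mixed regime (`sigma+rho < 2`, `sigma > 1`) its unique root `t*` is found
  by bracketing and Brent's method;
- `alpha1 = (t - sqrt(t))/(t-1)` and the roots `alpha3 < alpha4` of the
  concave quadratic `g2(alpha)`; these are computed from the expanded
  quadratic coefficients and cross-checked against the surd closed form
  with `p(t) = 9(t-1)^4 + t^2 ln^4 t - 10 t (t-1)^2 ln^2 t` (the two agree
  to ~1e-12; the expanded quadratic is primary because it avoids the severe
  cancellation inside `p(t)` near `t = 1`);
- `beta1`, the window-end value where the `V^2` coefficient of `I1d`
  changes sign when `alpha1 <= alpha < alpha4`, located by a 10^4-point scan
  plus Brent polishing;
- the discriminant `Delta` of `I1d`, reported both as the polynomial
  discriminant and through a five-part decomposition `Delta10..Delta14`
  written in the increments `X = dA·(dsigma,drho)`, `Y = A·dB·(...)`,
  `Z = z1(sigma-rho)A/((z1-z2)ln t)`; the decomposition is an exact identity
  (verified to 50 digits during development and to 1e-9 in the suite);
- the kernel `g4(alpha)` deciding the sign of `Delta` as the window shrinks
  (`beta -> alpha`). `g4` is evaluated from the exact `beta -> alpha` limit
  of the curvature of the scaled discriminant, which collapses to a closed
  (sigma, rho)-independent quadratic form in the limit derivatives of `A`
  and `B`. The fully expanded polynomial form of this kernel is unwieldy;
  the quadratic-form evaluation is exact and is dual-path tested against a
  Richardson-extrapolated finite-difference of the discriminant.

Critical potentials: `V01d/V02d = -intercept/slope` of `I0d`; the vertex
`V1c = -c1/(2 c2)` of `I1d`; the real zeros `V11d < V12d` (or
`V13d < V14d`) of `I1d` when `Delta > 0`, obtained from the numerically
stable quadratic formula and re-verified by bisection; and the reversal
potentials of the full relations with (`bd`) and without (`EN`) boundary
layers.

Two findings from implementing this apparatus exactly:

1. For the reference geometry (`a = 0.4`, `b = 0.48`, `r0 = 0.5`,
   `t = 1.5`), `alpha = 0.39887` lies **above** `alpha3 = 0.33861` and above
   `alpha* = 0.39531`: the linearized `I1d` has `Delta < 0`, is concave down
   for `sigma > rho`, and has **no real zeros** — for this channel the
   first-order boundary-layer correction never changes sign. The concave-up,
   two-zero picture requires a charge window located nearer the channel
   entrance (`alpha < alpha3`). The classifier reports the honest branch.
2. `g4` has a second sign change (near `alpha = 0.70` at `t = 1.5`) outside
   the window `(alpha3, alpha1)` where the shrinking-window classification
   uses it; `alpha_star` therefore reports every sign change it finds and
   commits only to the one inside that window.

## Numerical solver (finite eps)

`bvp.py` solves the full singularly perturbed system by collocation
(`scipy.integrate.solve_bvp`). The domain is split at the charge jumps into
`[0,a]`, `[a,b]`, `[b,1]`, each mapped onto a common coordinate; the four
state variables per segment plus the two global flux unknowns form one
14-component system with continuity of `(phi, h u, c1, c2)` imposed at the
interfaces — `Q` is constant per segment, so the discontinuity needs no
smoothing. The Poisson equation is integrated in `w = h(x) u`, since
`eps (h u)' = -h(z1 c1 + z2 c2 + Q)` involves no derivative of `h` at the
kinked junctions.

Numerical choices: collocation tolerance `1e-8`, at most 5000 mesh nodes,
initial mesh of 41 nodes per segment clustered at the segment ends (tanh
stretching) to resolve `O(eps)` layers; the starting guess is the outer
(eps → 0) solution — `c1` linear in `H(x)/H(1)`, `phi` following
`lam · ln c1` — with geometric continuation in eps from 0.1 down to the
target (factor 0.7, one automatic step halving on failure); voltage sweeps
and bisections warm-start each solve from the previous solution. `eps`
below `1e-3` is outside the supported range and rejected. A converged
solution with non-positive concentrations is rejected rather than returned.

Numeric critical potentials are zeros of the numeric zeroth-order
(`Q0 = 0`) and first-order (centered difference `(I(+Q0) - I(-Q0))/(2 Q0)`)
current curves, found by a coarse scan plus bisection that re-solves the
boundary-value problem per iterate.

Accuracy observed at the reference parameter set: with electroneutral
boundaries and `Q0 = 0` the collocation current matches the closed-form `I0`
to ~2e-6 relative at `eps = 0.01` (the gap scales like `eps^2` and is
asserted to shrink monotonically over `eps ∈ {0.05, 0.02, 0.01}`); with
relaxed boundaries (`sigma = 1.2`, `rho = 0.9`) the gap to the first-order
theory stays below 1e-4 at `V ∈ {-1, 0, 1}`.

## Reference parameter set

The defaults of `RunConfig` are the simulation conditions the package
reproduces: `z1 = -z2 = 1`, `D1 = 2.032`, `D2 = 1.334`, `L1 = 12`, `R1 = 8`,
`eps = 0.01`, `Q0 = 0.008`, `a = 0.4`, `b = 0.48`, `r0 = 0.5`, and the
cylinder-like profile `h(x) = pi (r0+a-x)^2 / pi r0^2 / pi (x+r0-b)^2` on
the three segments (continuous at both junctions). The relaxation factors
for the "with boundary layers" setup are not part of that published set; the
package defaults to `(sigma, rho) = (1.2, 0.9)`, chosen to satisfy
`sigma > rho`, `sigma > 1`, `sigma + rho > 2` (the increasing branch of
`I0d`) while staying within the `|sigma-1|, |rho-1| <= 0.25` radius where
the first-order expansion is meaningful. Both are configurable.

## Degenerate inputs and numerical hygiene

- `gamma(t) = (t ln t - t + 1)/((t-1) ln t)` uses a series branch
  (`1/2 + u/12 - u^2/24`, `u = t-1`) within `|u| < 1e-5`; note the exact
  identity `gamma(t) = 1 - 1/ln t + 1/(t-1)`, which shows the approach to
  its limits 0 and 1 is logarithmic in `t`.
- Equal effective concentrations (`c1L = c1R`, i.e. `theta = 0`) are a
  removable singularity of every flux formula. The kernel routes all
  differences through a shared factor `u = c1L - c1R` and `log1p`, and forms
  `1 - B` as `(A - ln(c10b/c10a))/A` from correlated terms, so direct
  evaluation stays accurate far inside the guard band `|theta| < 1e-8`;
  inside it, the value is the mean of two evaluations at log-ratio `±1e-5`
  (error `O(1e-10)`), and the exactly balanced equilibrium returns zeros.
- `L1 = R1` in the expansion module routes `f0` through its limit `L1`.
- Root finding throughout is scan-plus-Brent with `xtol` between `1e-14`
  (scalar thresholds) and `1e-4` (numeric critical potentials, where each
  function evaluation is a full collocation solve).

## What the tests do and do not show

The suite validates internal consistency (dual-path identities, derivative
oracles, Taylor order, threshold orderings) and the agreement between the
analytic eps → 0 theory and the finite-eps collocation solution on the
reference conditions. It does not validate the PNP model against measured
channel data: real channels have non-ideal electrochemical potentials,
three-dimensional geometry, and permanent charge that is neither small nor
piecewise constant. Two documented checks are knowingly red: the demand
that `gamma` reach its limits to 1e-9 at `t = 1e±12` (impossible given the
logarithmic approach), and the concave-up/two-zero signature of `I1d` at
the reference geometry (excluded by the theory's own thresholds, as
explained above; the remaining signatures — increasing `I0d` with a unique
zero, and the rightward shift `V01EN < V01bd` of the reversal potential,
confirmed by the collocation solver — do hold).

## Limitations

Two ion species only; first order in `Q0` and in `(sigma-1, rho-1)`; no
existence/uniqueness theory (the collocation solver verifies solutions
numerically); `eps >= 1e-3`; no time dependence.
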