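# Methods

## Model structure and assumptions

The package implements an eight-state ODE model of the glucose–insulin
regulatory system coupled to the β-cell cycle. Three feedback loops operate
on separated time scales: immediate release of stored insulin (minutes),
glucose-dependent provision of new insulin (tens of minutes), and adaptation
of β-cell mass through the cell cycle (days to weeks). Key assumptions:

* functioning β-cell mass is the G1-phase population; mass adapts by
  replication only (no neogenesis, transdifferentiation, or cell-size
  change);
* the apoptosis rate p4 is constant (no glucose-toxicity feedback);
* glucose enhances the G1→S transition linearly, `p1(1 + p5 G)`;
* insulin storage follows a packet-threshold picture: packets are
  interpreted as β-cells that are active (threshold below current glucose,
  pool X1) or inactive (pool X2), relaxing toward a sigmoid target
  distribution whose capacity Xmax = p12·G1 tracks cell mass;
* units are taken at face value from the published table (minutes,
  mg/100ml, mg, ml); in particular the 1/bv factor in the insulin equation
  carries no per-100ml conversion, and no unit-algebra layer is attempted.

## Canonical form of the storage dynamics

The storage rates are assembled from the detailed balance form (boundary
flux + secretion + redistribution + provision) using the closed-form
integrals of the target density:

```
A(G,G1) = Xmax G^k/(C^k+G^k),   B = Xmax C^k/(C^k+G^k),   A + B = Xmax
dX1/dt =  X1 (ξ*(G)/A) dG/dt − p9 X1 + f̃(A X2 − B X1) + f A P
dX2/dt = −X2 (ξ*(G)/B) dG/dt         + f̃(B X1 − A X2) + f B P
```

An equivalent published grouping in terms of transition functions u1…u4 is
typographically ambiguous in one term; the package treats the u-forms purely
as cross-check identities (u1 = f̃B, u2 = f̃A, u3·G1 = fA, u4·G1 = fB), which
the test suite verifies to machine precision at randomized states. Two
consequences worth noting:

* the combinations f̃A, f̃B, f̃Xmax are independent of G1 (f̃ scales as
  1/Xmax), so the assembled right-hand side is regular at G1 = 0 and the
  cell-free fixed point annihilates it exactly;
* the two boundary-flux terms are not equal-and-opposite unless
  X1/A = X2/B; the published reduction implies this and it is accepted at
  face value, so X1 + X2 is conserved by redistribution but not by the
  boundary exchange when glucose moves. This is a documented property of
  the model, not of the implementation.

The provision factor P is dimensionless with steady state
P∞(G) = G^h/(P0^h+G^h) ∈ [0,1); the implied time constant of the f·A·P mass
inflow is absorbed into f.

## Parameters

Defaults are the published table values. The per-cell insulin content is
recomputed as p12 = Xbar_max/G1(0) = 1.7223e-9 mg (the table rounds to
1.72e-9, a 0.2% difference) so that Xmax(G1(0)) = Xbar_max exactly and the
target distribution normalizes; a flag restores the printed value. Parameter
invariants enforced by validation: all constants positive; p4 > p1 (positive
glucose threshold Ĝ = (p4−p1)/(p1 p5)); f < p9, which keeps the shared
denominator f G^h(1+C^k G^−k) − p9(P0^h+G^h) of the redistribution factor
strictly negative for all G > 0 (asymptotically (f−p9)G^h) and hence f̃
positive and finite. The redistribution factor uses the time-varying
capacity Xmax(t) in its denominator, as printed.

## Steady states and stability

* Trivial fixed point F1* = (0,0,0, p6/p7, 0,0,0, P∞(p6/p7)).
* Euglycemic fixed point F2*: G* = Ĝ, I* = (p6−p7G*)/(p8G*),
  X1* = bv·p10·I*/p9, P* = P∞(G*) are pinned by the scalar balances; the
  remaining components are solved by damped Newton on the residual rows
  (dS, dG2M, dX1, dX2) — the dG1 row is algebraically implied at G = Ĝ —
  seeded with the closed forms G1* = p9X1*/(p12 f P*), S* = p4G1*/p2,
  G2M* = p4G1*/p3 and X2* from the dX2 = 0 balance. For the defaults the
  seeds are already a root to ~1e-19, and the capacity identity
  X1* + X2* = Xmax(G1*) holds exactly by construction of f̃. A long-horizon
  integration fallback covers Newton failure. Convergence is declared at
  relative residual < 1e-8 (measured against per-component scales).

The Jacobian is computed by central finite differences with per-component
steps `eps_rel·max(|x_j|, scale_j)` (default eps_rel 1e-6; scales from the
closed-form seeds, needed because the state spans ~14 orders of magnitude).
Before eigenvalue extraction the matrix is balanced by the diagonal
similarity S⁻¹JS with S = diag(scales), which leaves the spectrum unchanged
but avoids float round-off dominating the small eigenvalues. Classification:
stable iff all real parts < −tol, unstable iff any > +tol, else marginal,
with tol = 1e-12 × spectral radius. With defaults F1* is unstable
(λmax ≈ +3.4e-5 1/min) and F2* stable (real parts −0.679 … −1.52e-5 1/min);
the classification is invariant to eps_rel across [1e-7, 1e-4].

## Positivity

Solutions from positive initial data stay positive iff every component's
rate is positive on that component's zero face. The check evaluates each
component's rate (via its sub-model, so the G = 0 face uses dG/dt = p6
without touching the singular storage ratios) at x_i = 0 with the other
components sampled log-uniformly from ranges covering all simulated regimes
(cells 1–1e9, G 1–600 mg/100ml, I 1e-6–1, X1/X2 1e-9–1e-2 mg, P 1e-6–1);
log-uniform because each range spans several decades and the small-value
corners are where a sign defect would hide. Default 1e4 samples per face,
fixed seed 20121119. The positivity is in fact structural (each boundary
rate is a sum of positive terms), which the sampled minima make visible.

## Time integration

`scipy.integrate.solve_ivp` with the Dormand–Prince RK45 pair, rtol 1e-8 and
per-component atol (cells 1e-3, concentrations 1e-10, masses 1e-14,
P 1e-12), sampled on a fixed output grid (1 min for 120-min runs, 10 min for
96-h runs) so CSVs do not depend on internal stepping. A guard rail refuses
states with G ≤ 1e-6 mg/100ml (the boundary ratio ξ*/A ~ k/G is singular at
zero; biologically G > 0 by constant hepatic production): the
integrator-facing RHS returns NaN there, forcing step rejection and a loud
failure rather than silent continuation. No positivity clipping is applied —
positivity is a model property under test, not an enforced constraint; runs
fail on excursions beyond −1e-12 relative. Halving the tolerances moves the
physiological G(120 min) by < 1e-4 relative.

The type-1 scenario's apoptosis multiplier defaults to 10: the source only
prescribes "increase p4", and any multiplier pushing Ĝ above the attainable
glucose range produces the same qualitative β-cell decline; the CLI exposes
`--p4-multiplier`.

## Threshold-density oracle

An independent method-of-lines implementation of the packet-density
dynamics verifies the two-compartment reduction at constant glucose (its
exact validity domain; for moving glucose the published reduction has no
PDE-level counterpart to test against, which is a known limitation, not a
test failure). Numerical choices:

* uniform θ grid on [0, θmax], θmax = 2000 mg/100ml; the closed-form tail
  mass C^k/(C^k+θmax^k) ≈ 1.9e-4 must stay below 1e-3 (checked at grid
  construction);
* the threshold is snapped to the nearest node, and because the density is
  discontinuous there (secretion acts only below threshold) the node is
  carried twice — a below-side and an above-side value — keeping trapezoid
  quadrature second order in the spacing;
* the comparison reduction uses closed-form coefficients, with the
  non-releasable integral truncated consistently with the grid
  (B0 = Xbar_max[θmax^k/(C^k+θmax^k) − G^k/(C^k+G^k)]) so the measured
  discrepancy is pure discretization error rather than tail mass;
* the redistribution factor is frozen at f̃(G, G1(0)) and the provision
  input defaults to the constant-G provision solution
  P(t) = P∞(G)(1 − e^(−p11 t)).

At G = 150 mg/100ml, 2000 nodes, 200 min, the sup-norm relative discrepancy
is ≈ 1.2e-5 (< the 1e-4 gate), and doubling the node count reduces it by
the factor ≈ 4.0 expected of a second-order scheme.

## Problem sizes and horizons

Default test runs use the published horizons (120 min physiological/type-2,
96 h infusion/type-1). The stable state itself is approached on the β-cell
mass adaptation scale: the slowest eigenvalue at F2*, ≈ −1.52e-5 1/min,
gives an e-folding time of ≈ 6.6e4 min, and since the default initial
condition sits O(1) away in relative terms (G1(0) = 9.58e5 vs
G1* ≈ 1.73e8), a run of order 1e6 min is required to land within 1e-3 of
F2* component-wise (verified by direct integration; the suite asserts
convergence at that horizon). A 1e5-min run has shed only a factor
e^(−1.5) ≈ 0.22 of the deviation and still sits ~0.9 relative away on the
cell-cycle components, though its glucose gap |G − G*| is already small and
monotonically shrinking over the last decade of the run.

## Known limitations

* The oracle adjudicates the storage reduction only at constant glucose.
* The boundary exchange non-conservation (above) is inherited from the
  model as published.
* The model mixes a mouse blood volume with a rat-experiment infusion
  scenario; parameters are used as printed.
* Synthetic inputs only: the builtin scenarios emulate the studied regimes
  (post-prandial decay, sustained infusion, reduced insulin sensitivity,
  elevated apoptosis) but none of the measurement noise, meal structure, or
  inter-individual variability of real glucose/insulin data, so passing
  tests certify the dynamical-systems claims, not fit to data.
* No parameter estimation; the defaults are the published constants.
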