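# Methods

## 1. The 1D pulse-wave model

The solver integrates mass and momentum balance for cross-sectional area
A(x,t) (cm²) and volumetric flow q(x,t) (mL/s) on each vessel of a rooted
binary network:

    dA/dt + dq/dx = 0
    dq/dt + d/dx[ (γ+2)/(γ+1) q²/A ] + (A/ρ) dp/dx = −2πμ(γ+2)/ρ · (q/A)

The advective coefficient and the friction term come from a power-law axial
velocity profile u(r) ∝ 1 − (r/R)^γ; γ = 9 (default) gives the nearly flat
profile observed in vivo, so the advective coefficient is 11/10. Pressure
closes the system through the elastic tube law

    p = (4/3) (Eh/r₀) (√(A/A₀) − 1),    Eh/r₀ = k₁ e^(−k₂ r₀) + k₃,

with A₀ = πr₀². The square-root form is the constitutive law of this model
family; it yields the wave speed c(A) = c₀ (A/A₀)^¼ with c₀ = √(2s/3ρ)
(s the stiffness in dyn/cm²) and Riemann invariants u ± 4c, which the
boundary treatment uses throughout. Vessels are untapered; blood is
Newtonian with ρ = 1.055 g/cm³, μ = 0.049 g/(cm·s) (standard hemodynamic
values, configurable). All internal arithmetic is CGS; pressures convert to
mmHg (×1/1333.22) only at I/O boundaries, which avoids mixed-unit bugs in
the (A/ρ)∂p/∂x term.

### Discretization

Richtmyer two-step Lax–Wendroff in conservative variables (A, q); the
pressure-gradient term is folded into a flux antiderivative
B(A) = 4s A^{3/2} / (9ρ√A₀), exact for untapered vessels, so interior
updates need no geometric source terms. Defaults (chosen once for
desk-scale runtime while meeting the convergence checks below): 32 spatial
nodes per vessel, target CFL 0.5 (checked against 1 at every step, with an
automatic retry at halved Δt on violation), period T = 0.85 s, at most 8
cycles, periodicity tolerance 10⁻³ (max-over-signals relative L2 difference
between consecutive cycles), 256 output samples per period by periodic
linear interpolation, midpoint output at the node nearest L/2. Simulations
start from a DC warm start (uniform pressure CO·R_total, zero flow), which
removes most of the capacitive transient.

The scheme's observed self-convergence order on a smooth travelling wave is
≈ 2; boundary couplings are first-order in time (characteristics evaluated
at the foot of the incoming wave by linear interpolation), which in practice
leaves waveform changes < 1% when the grid is doubled.

### Boundary conditions

*Inlet*: prescribed periodic flow q(0,t); the inlet area follows from the
outgoing W⁻ invariant by scalar Newton.

*Junctions*: conservation of flow and continuity of total pressure
p + ρu²/2 between the parent and each daughter, solved together with the
three outgoing characteristic relations by a damped 3×3 Newton iteration
(convergence at the rounding floor; flow-conservation residuals are tracked
and stay below 10⁻¹⁰·max(|q|,1) in full simulations).

*Windkessel outlet*: dp/dt = Rp dq/dt + q(Rp+Rd)/(RdCT) − p/(RdCT),
discretized trapezoidally (the Rp dq/dt term integrates exactly), coupled
to the outgoing characteristic by scalar Newton. The discrete DC impedance
is Rp + Rd to 10⁻⁶ relative; the trapezoidal rule is second order.

*Structured-tree outlet*: the tree grows from the terminal vessel's radius;
a branch of radius r spawns daughters (αr, βr) while r > r_min, and every
spawned branch exists (daughters at or below r_min are leaves). Segment
input impedance uses the linearized Womersley transmission line: with
F_J = 2J₁(ζ)/(ζJ₀(ζ)), ζ = i^{3/2} r√(ρω/μ), compliance C = 3A₀/(2s),
wave speed c_ω = √(A₀(1−F_J)/(ρC)), characteristic admittance g = cC,
segment length ℓrr·r, and load Z_L:

    Z_in = (i tan(ωL/c)/g + Z_L) / (1 + i g Z_L tan(ωL/c))

Leaves are terminated with Z_L = 0; bifurcations combine in parallel. At
ω = 0 each segment contributes exactly its Poiseuille resistance
8μℓrr/(πr³) in series — a formulation-independent anchor verified against a
brute-force series/parallel reduction of the enumerated tree. Impedances
are memoized over the (i,j) radius classes r·αⁱβʲ (identical subtrees by
self-similarity); exponentially scaled Bessel functions keep the ratio
finite at high Womersley number. The spectrum is evaluated on the solver's
own harmonic grid (Nsteps/2+1 harmonics of the period) and inverted to a
real admittance kernel; the PDE coupling is the periodic discrete
convolution q_n = Δt Σ_j y_j p_{n−j}, solved implicitly with the outgoing
characteristic. Both terminal vessels share one parameter set
(α, β, ℓrr, r_min).

## 2. PCA output reduction

For each of the five analysis signals (MPA pressure, LPA/RPA flow, LPA/RPA
mid-vessel area) the training ensemble (N × 256) is row-centred and
decomposed by SVD; the top M = 5 right singular vectors form the orthonormal
basis η_q, scores are projections, and explained-variance fractions are the
normalized squared singular values. Scores are time-independent (the
truncated Karhunen–Loève form); component signs are fixed by making each
basis vector's largest-magnitude entry positive, for reproducibility. No
cross-signal (joint) PCA is attempted — each signal gets its own basis, so
cross-output correlation is not modelled.

## 3. Legendre polynomial-chaos surrogate

Parameters with independent uniform priors are mapped affinely to
ξ ∈ [−1,1]^P. The basis is the total-degree set {a : Σaᵢ ≤ m} of tensorized
Legendre polynomials, 𝒦 = C(P+m, m) terms. Internally the *orthonormal*
family ψ_j = √(2j+1) P_j (unit variance under the uniform density) is used,
so every normalization factor is 1 and all Sobol' sums are sums of squared
coefficients; the classical L² norm γ_j = 2/(2j+1) of the unnormalized
family is exposed for reference, and Sobol' ratios are identical under
either convention (the normalization ambiguity between the L² norm and the
probability-density expectation cancels in all variance ratios).
Coefficients are fit per PCA score column by SVD-based least squares
(never the normal-equations inverse); the fit records the design-matrix
condition number and per-component training R², and refuses
under-determined or rank-deficient designs. Defaults: degree m = 5 with
M = 5 components for production use; the desk-scale profile used throughout
the test suite and the acceptance script is m = 3 with 600 training /
50 test simulations, which already reaches sub-percent median MSRE on the
Windkessel model. Training designs are Latin hypercube with recorded seeds;
simulations that fail (blow-up or non-convergence) are dropped from the
ensemble and logged.

Surrogate accuracy is measured by the max-normalized mean square relative
error per test sample, e_i = mean_t[(Y_i(t) − Ŷ_i(t))/max_t Y_i(t)]²,
summarized by its mean or median over samples.

## 4. Sobol' indices from coefficients

With orthonormal polynomials, Var[c_q] = Σ_{k≥1} z_qk², and

    S_iq  = Σ_{k∈A_Si}  z_qk² / Var[c_q],
    ST_iq = Σ_{k∈A_STi} z_qk² / Var[c_q],

where A_Si holds multi-indices active only in dimension i and A_STi those
active in i. Pointwise-in-time indices for the reconstructed signal add the
cross-component covariance terms:

    S_iY(t) = [Σ_q S_iq Var[c_q] η_q² + 2Σ_{q<q*} (Σ_{k∈A_Si} z_qk z_q*k) η_q η_q*] / Var[Y](t)

and the total-order index is the complement 1 − Var[E[Y|θ₋ᵢ]]/Var[Y], where
the conditional expectation keeps exactly the non-constant multi-indices
with a_i = 0 (the conditional mean of any ψ with a_i > 0 vanishes). The
denominator Var[Y](t) is computed from the same coefficient algebra, so the
identity between the pointwise and component formulas is exact by
construction; this is pinned by a full-basis oracle test (pointwise indices
equal independent per-timepoint PCE indices to 10⁻⁶). Because the PCA basis
is truncated, pointwise totals can exceed [0,1] by a small margin on the
real model; the test suite bounds the excursion at a few percent.
Components whose coefficient variance sits at the least-squares rounding
floor are reported as NaN (indices undefined for a constant output).
Parameter ranking uses max-over-time ST_iY with a configurable influence
cutoff (default 0.01 — any such cutoff is heuristic).

## 5. Profile-likelihood identifiability

The objective is the design-weighted sum of squares
g(θ) = Σ_s Σ_t (y_s(t) − M_s(t;θ))²/w_s with w_s the time-average of signal
s's data — a nondimensionalization that balances pressure (mmHg), flow
(mL/s) and area (cm²) blocks in the noise-free setting; in a real inverse
problem w_s would be the measurement variances, and the same code accepts
explicit weights. Designs: D1 = {MPA pressure}, D2 = D1 + {LPA, RPA area},
D3 = D1 + {LPA, RPA flow}.

The MLE minimizes g by Levenberg–Marquardt (finite-difference step 10⁻⁴,
at most 300 iterations per parameter dimension) with 5 seeded multistarts
inside the prior box. Each parameter is profiled on a 41-point grid over
±50% of its MLE value, sweeping outward from the MLE and warm-starting each
re-optimization from its neighbour; optimizer failures are recorded as
missing, never interpolated. The optimizer is bound-free (profile grids stay
positive by construction); predictions outside the prior box are polynomial
extrapolations of the surrogate and flagged by the prediction API.

The confidence interval is the contiguous sub-level set of the profile
under g_MLE + Δ(a)/2, Δ(a) = icdf(χ²₁, 1−a) (3.8415 at a = 0.05), with
bounds interior to the grid located by linear interpolation. Both bounds
interior → identifiable; one → one-sided; curve entirely below the
threshold → flat. With the weight convention above, g equals twice the true
Gaussian negative log-likelihood when w_s = 2σ²; under that identification
the profile CI on a linear-Gaussian problem is exactly θ̂ ± z_{1−a/2}·SE,
which the test suite verifies. The workflow helper repeats MLE + profiling
per design while cumulatively fixing parameter subsets *at their inferred
values* (not at any a-priori truth), and profiled optima can be re-evaluated
through the full PDE simulator to check that surrogate-based conclusions
survive.

## 6. Synthetic study conditions

No external data is consumed. The fixtures emulate a normal adult pulmonary
circulation:

| quantity | value | why |
|---|---|---|
| geometry | MPA 5.0/1.35, LPA 3.0/0.93, RPA 4.0/0.95 cm | plausible adult dimensions |
| inflow | T = 0.85 s, CO = 90 mL/s, systolic fraction 0.35, 10% diastolic baseline | representative MPA magnitude/shape; C¹-periodic, mean exactly CO |
| wall | k₁ = 10 mmHg, k₂ = 2 cm⁻¹, k₃ = 30 mmHg | pulse-wave speed ≈ 1.7 m/s; exponential term a small stiffness correction |
| Windkessel | Rp1/Rd1 = 0.05/0.32, Rp2/Rd2 = 0.04/0.26 mmHg·s/mL, CT1/CT2 = 1.2/1.5 mL/mmHg | ~45/55 LPA/RPA flow split, mean MPA pressure ≈ 15 mmHg |
| Structured tree | α = 0.88, β = 0.66, ℓrr = 50, r_min = 0.01 cm | standard pulmonary tree scalings; r_min at the desk-scale end to cap tree size |
| priors | uniform, ±50% around nominal | matches the profiling range |

These are stand-ins chosen once, not measurements; the waveform is a
raised-sine pulse rather than a measured flow trace, so it lacks the dicrotic
features of real MPA flow, and the network omits taper and downstream
branches. Consequently the passing tests demonstrate the *method chain* —
solver correctness, surrogate accuracy, the coefficient algebra, and the
design ranking D3 > D2 > D1 — at physiologic operating points, not
agreement with any specific measured dataset. Quantities that depend on the
unprinted geometry/priors of real studies are asserted as bounds (e.g.
five components capture ≥ 99% of every signal's variance) rather than as
exact values.

The analytic toy registry anchors the oracles: a polynomial with exact
ANOVA indices S = (3/16, 12/16), ST = (4/16, 13/16); an additive
time-varying case with closed-form pointwise indices; a linear-Gaussian
regression with known CIs; and a symmetric structured tree with series/
parallel DC resistance.

## 7. Numerical choices and degenerate inputs

- Newton solvers (inlet, junction, outlets) converge to the rounding floor
  with damping that preserves area positivity; persistent failure aborts
  the simulation with a status the driver converts into typed exceptions.
- The time step is chosen from a conservative speed estimate per parameter
  sample; a CFL violation triggers one automatic retry at halved Δt, and
  samples that still fail are dropped from ensembles (standard practice for
  surrogate training).
- PCA of a rank-deficient ensemble yields zero trailing fractions; requesting
  M ≥ min(N, Nt) is an error.
- MSRE is undefined for a signal whose maximum is zero (error).
- Profile curves whose minimum exceeds the reported g_MLE indicate
  inconsistent inputs and raise instead of classifying.

## 8. Problem sizes

The test suite and the acceptance script use 200 simulations for the PCA
variance experiments, 600/50 train/test simulations at degree 3 for
surrogate validation, and the 600-sample surrogate for the identifiability
ladder — sizes chosen so the whole pipeline reruns from scratch in minutes
on one CPU while leaving every qualitative conclusion unchanged from larger
runs. Production-scale settings (degree 5, thousands of training runs)
are a constructor argument away.

## 9. Known limitations

- Univariate profiles only; profile-wise multivariate likelihood analysis is
  out of scope.
- No measurement-noise model: the likelihood weighting is a
  nondimensionalization, so absolute CI widths inherit its scale; the
  classification (flat / one-sided / identifiable) is the robust output.
- Per-signal PCA ignores cross-output correlation.
- The structured-tree segment model assumes linearized, axisymmetric,
  viscous-dominant periodic flow; only the DC limit is formulation-
  independent.
- Tapered or curved vessels, viscoelastic walls, non-Newtonian rheology,
  shock capturing, and venous trees are out of scope.
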