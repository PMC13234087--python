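# Methods

## Model structure

The circulation is a single closed loop of lumped compartments:

- **Systemic circulation** — aortic root (a storage-free junction), a
  proximal characteristic impedance `z_sys_prox` into an arterial
  compliance `c_sys_ar`, a distal resistance/inductance `r_sys_dist` /
  `l_sys_ar`, a venous compliance `c_sys_ven` and venous resistance
  `r_sys_ven` into the right atrium.
- **Pulmonary circulation** — arterial and venous R/C/L segments between
  the pulmonary valve and the left atrium.
- **Coronary circulation** — proximal resistance from the aortic root into
  a compliance whose external pressure is `k_im`·P_LV (intramyocardial
  squeeze; default k_im = 0.5), then a distal resistance into the right
  atrium. The synthetic patient's coronary resistances are chosen so the
  mean flow is near the 0.8 mL/min-per-gram perfusion target for its LV
  mass (the helper `coronary_flow_target` exposes the rule).
- **Right heart** — atrium and ventricle as time-varying elastance
  chambers, P = [E_min + (E_max − E_min)·a(t)]·(V − V0), with a C¹
  raised-cosine activation a(t) (0→1 over a rise time, 1→0 over a fall
  time). The functional form of a(t) is a design choice; any smooth
  periodic activation in [0, 1] works.
- **Left heart** — LA and LV volumes are *prescribed* periodic waveforms
  (the use case is imaging-derived chamber volumes), interpolated by a
  periodic cubic spline. Their pressures are algebraic unknowns determined
  by flow balance. This reproduces imaging-consistent kinematics but means
  the left heart cannot respond to load (see Limitations).

The monolithic unknown vector has 25 entries: 10 differential circuit
states (4 compliance pressures, 3 inductive flows, right-heart and
coronary volumes), 6 algebraic pressures (aortic root, LA, LV, RA, RV,
coronary), 4 valve opening states, 4 transvalvular flows and the pump
flow. The 23-entry parameter vector exposed to personalization holds the
vascular R/C/L values, the four right-heart elastance extremes and the
four regurgitant orifice areas; activation timings and unstressed volumes
are fixed chamber settings.

Internal units are Pa, mm³ and mm³/s (the published HeartMate-3 pump
coefficients are in these units); user-facing values are mmHg, mL, L/min.

## Valves

Opening state: dg/dt = C1·sgn(α)/2·[1 + α(1 − 2g)], α = tanh[C2·ΔP_fwd +
C3·(Q + τ·dQ/dt)], with C1 = 800 s⁻¹, C2 = 10⁻³ Pa⁻¹, C3 = 10⁻⁴ s/mm³.
ΔP_fwd is the forward-driving pressure (upstream minus downstream), so
positive α opens the valve. Saturated transitions complete in
ln(99)/C1 ≈ 5.7 ms, about 1% of a 1 s cycle.

τ (default 0.02 s) sets the horizon of the flow-deceleration term. The
term is meant to anticipate flow reversal (valves start closing during
deceleration); with a horizon of order 1 s it would dominate the switching
signal whenever flow changes on sub-second scales — i.e. always — and the
model chatters. 20 ms is the scale of the isovolumic phases and of the
blood column's inertia at the annulus.

Effective opening G = max(g, g_min); open area A(G) = π·l_a·l_b·G² (an
ellipse whose semi-axes shrink proportionally with G); flow through it is
a Bernoulli orifice, Q = sign(ΔP)·A·√(2|ΔP|/ρ). The regurgitant floor is
g_min = √(ROA/(π·l_a·l_b)), the exact inverse of the area law. Valve
repair sets g_min = 0 and changes nothing else, isolating the causal
hemodynamic effect of the intervention.

## Time integration

One-step θ-scheme (θ = 0.5: midpoint, second order; verified on an RC
benchmark with the closed-form discharge curve): M(yⁿ − yⁿ⁻¹) =
Δt[θf(yⁿ) + (1−θ)f(yⁿ⁻¹)] for differential rows, pure algebraic rows
enforced at the new time level. Per step all rows are solved together by
a damped Newton iteration (finite-difference Jacobian over the 25-entry
vector, vectorized into one residual evaluation; LU solve), to a
row-scaled residual norm below 10⁻⁶. Rows are nondimensionalized by
typical magnitudes (10⁴ Pa, 10⁵ mm³/s, 10⁵ mm³) because raw rows mix
units.

Numerical choices that matter:

- **Prescribed-chamber balance rows in exact-increment form.** The LA/LV
  flow-balance rows equate the θ-weighted flow mix to the *exact* waveform
  increment (V(tₙ) − V(tₙ₋₁))/Δt rather than the instantaneous dV/dt. All
  compartment updates then telescope, so total blood volume is conserved
  to the Newton tolerance (measured drift ≈ 10⁻¹³ relative per cycle).
- **Semi-implicit switching signal.** α is evaluated at the previous time
  level; the g-row is then linear in gⁿ with a damping slope, and Newton
  handles it exactly. (A fully implicit α with a sharply smoothed sign
  function makes Newton chatter.) sgn(α) is smoothed as tanh(α/0.05)
  inside the solver: the ODE's rate magnitude is C1/2 for arbitrarily
  small |α|, so an exact sign chatters around zero pressure gradient
  (e.g. at the tricuspid during diastasis). The public `valve_rhs`
  defaults to the exact sign.
- **Filtered dQ/dt.** Transvalvular flows are algebraic, so their raw
  backward differences carry step-level jumps during transients; the
  dQ/dt input of α is low-pass filtered with a 5 ms time constant
  (physical closing decelerations act over ~100 ms and pass through).
- **Orifice-law regularization.** The √|ΔP| slope is finite-ized near
  ΔP = 0 (dp_eps = 0.5 Pa); relative error < dp_eps/|ΔP| away from the
  crossing.
- **Valve-state bounds as an active set.** g is clamped to [0, 1]; when a
  bound is active and the ODE pushes outward, that row is dropped from the
  Newton system (complementarity) so the clamp itself is the solution.
- **Sub-stepping.** If a step fails to converge (valve transitions under
  pump suction are genuinely violent), it is recursively halved up to 64×;
  the output grid is unchanged.

Default dt = 1 ms resolves the ~6 ms saturated valve transitions with
several steps; a typical step needs 2 Newton iterations. Periodic steady
state: strictly less than 5% change of every cycle-mean pressure and flow
between successive cycles, minimum three cycles; the default patient
settles in 4 cycles.

## Personalization

J(θ) = Σ ½((ŷᵢ − yᵢ)/yᵢ)² over the named target table. The fit runs a
fixed budget of projected gradient-descent iterations (robust far from the
optimum; default 50) and then Levenberg–Marquardt on the residual vector
with box projection. Two constraints:

- **Total blood volume** must match the Nadler estimate (sex-specific
  cubic-in-height formula). Enforced as a quadratic penalty row with
  weight 100 (configurable). TBV is evaluated at the resting initial
  state, where stressed volumes Cᵢ·P_init depend on the candidate
  compliances — that is what makes the constraint bind on θ.
- **Regurgitant orifice areas** are box-bounded by severity class
  (defaults: none [0,0], mild (0,20], moderate (20,40], severe (40,80]
  mm²; a configuration table, not a clinical standard).

Non-convergent simulations return a large finite cost (10⁶ + residual
norm) so the optimizer retreats. With noise-free synthetic targets the
fit recovers a perturbed 3-parameter subset to ≪1% and drives J below
10⁻¹⁸; fitting loops use a coarse integrator (dt = 4 ms) — the problem
sizes used throughout the tests are chosen so the whole recovery loop
stays a few dozen simulations.

The ±10% one-at-a-time sensitivity analysis re-simulates each perturbed
parameter and reports relative output changes (NaN where the baseline
output is ~0); it is bit-reproducible.

## The synthetic patient

The generator emulates what the pipeline would receive from a real
LVAD-supported patient: LA/LV volume waveforms sampled at 10 ms (as if
10 CT phases were upsampled; piecewise raised-cosine segments with early
filling, diastasis, atrial kick and ejection; LV 180/155 mL — the minimal
deformation of a failing, unloaded ventricle), a ground-truth parameter
vector, a HeartMate 3 at 5400 RPM, valve floors from ROAs 44/6/25/5 mm²
(MV/AV/TV/PV), and a 20-entry clinical target table (systemic and
pulmonary pressures, PCWP, RA pressure, RV EDP and volumes, forward CO,
pump flow, LVEDP, aortic pulse pressure, regurgitant volumes, coronary
flow, E-wave proxy) read from the converged simulation and optionally
perturbed by multiplicative Gaussian noise at a fixed seed. The systemic
venous unstressed volume is chosen once so that TBV(θ*) equals the Nadler
volume of the patient's stated height/weight/sex. The resting initial
pressure distribution is that of a congested LVAD circulation (venous
14 mmHg), which both matches the clinical picture and starts the run near
its operating point.

What the generator does *not* emulate: measurement systematics (it uses
unbiased multiplicative noise), beat-to-beat variability, respiration,
baroreflex adaptation, or anatomically realistic waveform detail beyond
C¹-smooth phase structure. Passing tests therefore show the pipeline is
self-consistent and identifiable under its own assumptions — not that it
reproduces any individual patient.

## Baseline physiology and repair experiments

At baseline the default patient runs: pump 5.0 L/min, forward CO
3.6 L/min (the difference recirculates through the 6 mm² aortic leak),
MAP ≈ 70 mmHg, PCWP ≈ 13 mmHg, aortic valve permanently closed, nearly
flat aortic pressure. Repair experiments change only g_min: mitral repair
eliminates MR, raises forward CO and — because systolic ejection can no
longer escape into the LA — drives LV pressure above aortic pressure,
opening the AV (~0.24 mL/beat) and restoring pulsatility; aortic repair
eliminates AR and raises forward CO but does not open the valve; combined
repair does both and yields the highest forward output. These orderings
are structural properties of the model and are asserted in the test suite.

## Known limitations

- A 0D transvalvular flow is algebraic (no fluid inertia), so once
  ejection starts the switching signal sweeps through its transition band
  almost instantly: the measured systolic MV closure takes ~2–3 ms,
  whereas a 3D fluid model spreads the same closure over ~10 ms. Valve
  *transition speed* properties hold (saturated transitions ≈ 1% of the
  cycle), but closure-event durations are systematically shorter than in
  3D.
- Prescribed LA/LV volumes cannot adapt to load: every repair scenario
  reuses identical chamber kinematics, which isolates causal effects but
  forbids remodeling/contractility responses; with all outflow paths
  sealed, chamber pressure is set by the pump characteristic alone and can
  transiently go negative (suction), which the sub-stepping handles.
- Fixed-speed static H–Q pump: no dynamic pump response, speed modulation
  or suction detection.
- No septal interaction, pericardial constraint, baroreflex or
  autoregulation; the right heart is a reduced elastance model.
- The severity→ROA bounds table and the coronary intramyocardial factor
  are configuration defaults, not measured quantities.
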