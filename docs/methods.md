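# Methods

## Model and assumptions

The package models the net fluid shift between the intravascular and
interstitial compartments as proportional feedback control. The states are
the blood-volume change ΔV_B and its target r_B, with net input
w(t) = u(t) − v(t):

    dΔV_B/dt = w + K (r_B − ΔV_B),      dr_B/dt = w / (1 + α),
    ΔV_B(0) = r_B(0) = 0.

The inter-compartment flow is q = K(ΔV_B − r_B): fluid leaves the
vasculature exactly when the blood-volume change exceeds its target. The
model is linear and time-invariant; its assumptions are that (i) the
myriad microvascular mechanisms summarize into a single constant ratio α
between interstitial and intravascular volume changes, (ii) the shift rate
is proportional to the volume discrepancy with a single constant gain K, and
(iii) there is no intracellular compartment, no osmolality or protein
kinetics, and no time variation of α (in reality α likely peaks during the
transient and relaxes to a steady-state value; a fixed α pushes the fitted
V_B0 above its physical value to compensate — a known interpretive caveat
for crystalloid fits).

Outputs are reported as the fractional blood volume V̆_B = ΔV_B/V_B0, which
is what hemoglobin-dilution measurements deliver. All internal units are ml
and min; K is in 1/min (protocol clocks are in minutes throughout).

## Parameters

| name | units | default / bounds | role |
|---|---|---|---|
| α | — | fit bounds (1e−3, 50] | steady-state split: retain 1/(1+α), shift α/(1+α) |
| K | 1/min | fit bounds (1e−4, 10] | relaxation rate of the discrepancy e_B (time constant 1/K) |
| V_B0 | ml | fit bounds [500, 10000] | baseline blood volume; output normalizer |

The bounds are generous physiological envelopes: α up to 50 covers
volume-overloaded states where nearly all infused fluid leaves the
vasculature; V_B0 from 500 ml (severe hemorrhage, small subjects) to 10 l.

## Simulation

Piecewise-constant schedules admit a closed form per segment: with constant
w, the discrepancy e = ΔV_B − r_B relaxes exponentially,
e(t) = e₀e^(−KΔt) + wα/(K(1+α))(1 − e^(−KΔt)), while r_B grows linearly.
The simulator propagates (r_B, e) exactly across segment edges and evaluates
the closed form inside segments, so trajectories are exact to round-off and
no adaptive integrator is needed (the originally planned fallback was never
required). The interstitial change ΔV_ISF is reconstructed by cumulative
trapezoidal integration of q on the output grid — deliberately a quadrature,
mirroring how it would be reconstructed from a fitted model in practice — so
volume conservation ΔV_B + ΔV_ISF = ∫w holds to quadrature tolerance
(measured ≤ 0.014% of infused volume on minute grids for all reference
protocols) rather than identically.

The Euler difference-equation form discretizes the equivalent second-order
input/output description with backward differences on both the trace and the
inputs and the forcing two samples back, seeded with V̆(0) = V̆(−1) = 0 and
u = v = 0 before t = 0. The typeset recursion's index alignment was
confirmed by measuring its convergence: empirical order ≈ 1.04 against the
closed form over T_S ∈ {4, 2, 1, 0.5} min, i.e. consistent first-order
behaviour as printed, so no re-indexing was needed. The recursion's
characteristic roots are 1 and 1 − K·T_S; a warning is raised when
K·T_S ≥ 2 (instability). This path exists for cross-validation and for
users who want the discrete form; the continuous simulator is the
implementation path everywhere else, because differentiating
piecewise-constant inputs is impulsive and needs no approximation in the
state-space form.

## Hemodilution conversion

V̆_B(t) = [1/(1−Hct(t))]·[Hgb(0)−Hgb(t)]/Hgb(t). The time-varying
hematocrit is the default (`hct_mode="measured"`); the classical convention
of freezing the plasma correction at Hct(0) is available as
`hct_mode="baseline"`, since sources differ on which convention underlies
published analyses. The formula uses only concentration ratios, so g/l vs
g/dl is irrelevant to the result; the unit flag normalizes stored values and
error messages. No correction is made for phlebotomy losses or analyzer
drift.

## Estimation

`fit_model` minimizes the raw sum of squared residuals between the measured
and simulated V̆_B at the trace's sample instants, using bounded
`scipy.optimize.least_squares` in log10 parameter space (positivity and
scale equalization: K ~ 5e−2 vs V_B0 ~ 5e3). Multistart: the
regression-based estimate first (when admissible), then log-uniform random
starts from a seeded generator (default 8 starts, seed 20160831); the best
converged start wins, and per-start diagnostics are returned. The forward
model inside the fit is the exact continuous simulator rather than the Euler
recursion, which removes discretization bias from the estimates; the
equivalence of the two forms is enforced by tests instead.

The linear-regression route writes the second derivative of V̆_B as
θᵀ[V̆̇_B, u̇−v̇, u−v] with θ = (−K, 1/V_B0, K/(V_B0(1+α))); the first
element's sign is a convention (the physical gain is positive), and the
inverse map reports K = |θ₁|, V_B0 = 1/θ₂, α = Kθ₂/θ₃ − 1. Trace
derivatives use second-order central differences. Input derivatives are
per-segment: zero inside segments, with each rate step placed as a single
difference Δw/T_S on its breakpoint row. That placement matters: the central
second difference of the trace registers the slope jump caused by a rate
step in exactly that row, so this convention keeps step rows consistent and
the whole scheme second-order (noiseless recovery at T_S = 1 min is within
1% per parameter), whereas centrally differencing the sampled inputs splits
the jump across two rows and biases the estimate severely. Finite
differencing amplifies noise, so the regression is an initializer and
identifiability diagnostic only, never the final estimator. A trace with no
excitation raises a non-informative-data error.

Goodness of fit follows the normalized convention: per-sample errors and the
root-mean-squared error are both divided by the time-average of the measured
trace and reported in percent (RMSNE). These metrics are invariant to time
rescaling and to jointly rescaling both traces.

## Sensitivity analysis

The net-input → V̆_B transfer function is
G(s) = (s + K/(1+α)) / (V_B0·s·(s + K)). The normalized sensitivities are
computed from closed forms derived symbolically from G: S_VB0 ≡ −1,
S_K = −αKs/(((1+α)s+K)(s+K)), S_α = −αK/((1+α)((1+α)s+K)). Rather than
trusting any typeset source, the test suite checks all three against a
4th-order finite-difference derivative of `transfer_function` itself (step
1e−3 relative, balancing O(h⁴) truncation against 1/h round-off; worst
observed gap ≈ 1e−9 relative over ω ∈ [1e−4, 1] rad/min for all reference
parameter sets). ω = 0 is rejected explicitly — G has an integrator pole
there. Default grid: 200 log-spaced points over [1e−4, 1] rad/min.

## Protocol fixtures and synthetic data

Seven reference bolus protocols are encoded (three Ringer's acetate arms
under 0/450/900 ml pre-infusion hemorrhage; saline and Ringer's lactate;
albumin and autologous plasma) together with the parameter sets and error
metrics obtained by fitting the model to the corresponding protocol-average
published responses. Design choices:

* **Default weight 75 kg** — the source studies report only ranges
  (65–95 kg); any fixture can override it.
* **Urine defaults to zero** — per-protocol urine totals are not available,
  so fixtures omit the loss term; a `total_urine_ml` hook spreads a total
  uniformly over the study duration (the same simplification the source
  protocols force, since only totals were recorded). This is a deviation
  from the source studies, which did include urine output.
* **Pre-infusion hemorrhage is not placed in v(t)** — it precedes the study
  clock and is carried entirely by the lower fitted V_B0 of the
  corresponding parameter set, mirroring how the reference table's V_B0*
  falls from 4.86 l to 3.27 l across hemorrhage arms.

The synthetic-trace generator samples the exact response every 10 min (the
reporting interval of the source studies) and adds independent additive
Gaussian noise to every sample — the simplest model consistent with
hemodilution measurement error; noise sd 0.005 on V̆_B (~2–5% of typical
response amplitudes) is the reference condition for recovery experiments.
What the generator does *not* emulate: serially correlated measurement
error, inter-subject variability around the protocol average, time-varying α
or K, and urine dynamics. Passing recovery tests therefore demonstrate the
estimator's correctness and noise robustness under the model's own
assumptions, not the model's adequacy for any particular real dataset — the
latter is exactly what fitting real digitized curves
(`scripts/validate_digitized.py`) probes.

## Numerical choices and degenerate inputs

* Optimizer tolerances: xtol = ftol = gtol = 1e−12 (log10 space); the
  objective is reported unnormalized.
* Simulation grids are validated (start at 0, strictly increasing, inside
  the schedule); schedules validate non-negative rates and strictly
  increasing breakpoints starting at 0.
* Traces must satisfy V̆_B > −1 (blood volume cannot go negative);
  uniform-grid operations verify uniformity to 1e−9 relative.
* θ₂ ≤ 0 or implied α ≤ 0 from the regression raise an
  inadmissible-regression error rather than returning unphysical parameters;
  flat traces raise non-informative-data errors; a zero-mean measured trace
  makes normalized errors undefined and raises.
* Problem sizes: acceptance recomputations use minute-resolution grids for
  conservation checks, 501-point grids over ten time constants for the
  closed-form check, 20 replicates for recovery — sizes at which every
  quantity is stable to well below its tolerance.

## Known limitations

* α and K are constants; responses whose effective α drifts during the
  transient will bias V_B0 upward (see above).
* Protocol-average fitting only: no repeated-measures or hierarchical
  machinery for multi-subject data, and no confidence intervals — point
  estimates with residual diagnostics.
* The urine term supports constant rates only.
* The hemodilution route inherits hemoglobin-assay inaccuracy at large
  volume changes; no drift correction is attempted.
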