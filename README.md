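# fluidshift

Lumped-parameter modelling of blood-volume response to fluid infusion and
loss.

When a crystalloid or colloid fluid is infused intravenously, only part of it
stays in the circulation; the rest shifts across the capillary walls into the
interstitium at a rate governed by a tangle of Starling forces, vessel
permeability and endocrine signalling. `fluidshift` sidesteps that
microscopic complexity with a three-parameter feedback model of the
macroscopic fluid shift, intended for researchers and engineers working on
fluid-resuscitation monitoring and volume kinetics who need a model simple
enough to fit to an individual subject's hemodilution data.

## The model

The fluid shift is represented as the output of a hypothetical proportional
controller that regulates the ratio of interstitial to intravascular volume
change at a target value α. With infusion rate *u(t)* and loss rate *v(t)*
(ml/min), the blood-volume change ΔV_B (ml) obeys

    dΔV_B/dt = u − v − q,         q = −K e_B,      e_B = r_B − ΔV_B,
    r_B(t)   = 1/(1+α) ∫₀ᵗ (u − v) dτ,

so fluid flows between the compartments (flow *q*, ml/min) at a rate
proportional to the discrepancy between the actual volume change and its
target r_B. At steady state the controller retains the fraction 1/(1+α) of
the net input intravascularly and shifts α/(1+α) to the interstitium. Three
subject-specific constants characterize everything:

| parameter | meaning | units | typical |
|---|---|---|---|
| α | target volume ratio (interstitial : intravascular) | — | 2–4.5 crystalloids, 0.3–0.5 colloids |
| K | feedback gain — speed of the fluid shift | 1/min | 0.03–0.15 |
| V_B0 | baseline blood volume (normalizes the output) | ml | 3000–5600 |

The measured quantity is the fractional blood volume V̆_B = ΔV_B/V_B0,
obtained from hemoglobin dilution:
V̆_B(t) = [1/(1−Hct(t))]·[Hgb(0)−Hgb(t)]/Hgb(t).

The package provides:

* **`fluidshift.model`** — exact (segment-closed-form) simulation of
  arbitrary piecewise-constant infusion/loss schedules, plus the first-order
  Euler difference-equation form;
* **`fluidshift.hemodilution`** — Hgb/Hct series → V̆_B traces (and the
  inverse, for synthetic laboratory data);
* **`fluidshift.estimation`** — subject-specific estimation of (α, K, V_B0)
  by bounded multistart nonlinear least squares, with a linear-regression
  identifiability route as initializer, and normalized error metrics (RMSNE);
* **`fluidshift.sensitivity`** — analytic frequency-domain parametric
  sensitivities of the input→V̆_B transfer function;
* **`fluidshift.protocols`** — seven reference bolus-infusion protocols with
  fitted parameter sets, synthetic-trace generation and seeded
  parameter-recovery experiments;
* **`fluidshift.cli`** — a `fluidshift` command with `simulate`, `convert`,
  `fit`, `sense` and `recover` subcommands over CSV/JSON files.

## Worked example

Fit the model to a noisy synthetic saline bolus (25 ml/kg over 30 min into a
75 kg subject, 210 min observation, 10-min sampling, measurement noise
sd 0.005 on V̆_B):

```python
import fluidshift as fs

truth = fs.reference_params("saline")            # α=2.35, K=0.047, V_B0=5.56 l
sch = fs.schedule_from_protocol(fs.PROTOCOLS["saline"])
trace = fs.generate_synthetic_trace(truth, sch, T_S=10.0, noise_sd=0.005, seed=42)
fit = fs.fit_model(trace, sch)
print(f"alpha* = {fit.params_star.alpha:.3f}   K* = {fit.params_star.K:.4f} /min   "
      f"V_B0* = {fit.params_star.V_B0/1000:.2f} l   RMSNE = {fit.rmsne:.2f}%")
```

prints

```
alpha* = 2.426   K* = 0.0515 /min   V_B0* = 5.38 l   RMSNE = 3.37%
```

i.e. with realistic measurement noise the fit recovers the generating
parameters within a few percent, and the model reproduces the noisy trace to
3.4% of its time-average. The same pipeline from the shell:

```bash
fluidshift simulate --schedule schedule.csv --params params.json --ts 10 --out trace.csv
fluidshift fit --trace trace.csv --schedule schedule.csv --out result.json
fluidshift sense --params params.json --out spectrum.csv
```

The sensitivity spectra explain *how* fitting allocates the data between the
parameters: the normalized sensitivity to V_B0 is exactly −1 at every
frequency, the sensitivity to α approaches α/(1+α) at low frequency (the
steady-state plateau), and the sensitivity to K is confined to a
mid-frequency band (the transient) — so V_B0 shapes the whole response, α
the plateau, and K the speed of relaxation between them.

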