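# forminproc

Kinetic modelling and survival analysis of **formin processivity** at
actin filament barbed ends.

Formins are homodimeric actin polymerases: the FH2 dimer encircles the
growing barbed end and tracks it while the flexible FH1 domains deliver
profilin-actin. How long a formin stays on the end — its processivity,
quantified by the dissociation rate k_off — sets the length of the
filaments it makes. Single-filament microfluidics experiments show that
k_off depends on actin and profilin concentration, ionic strength,
fluorophore labeling, and most dramatically on pulling force: piconewton
tensions accelerate dissociation by orders of magnitude.

`forminproc` is written for biophysicists who analyse (or want to design)
such single-filament experiments. It provides:

* a closed-form **two-route kinetic model** of the barbed-end-bound FH2
  dimer: a rapid open/closed equilibrium (only the open state accepts
  subunits), an *open-route* dissociation clock, and a *transition-route*
  dissociation trial fired at every subunit addition, each route with its
  own Bell force law `k(f) = k0 · exp(f·δ/kBT)`; profilin occupancy of
  the barbed end (from solution, and via the FH1-mediated "ring complex")
  pauses elongation and protects against dissociation;
* an **exact stochastic simulator** of single formin-bound filaments
  under zero, constant, or length-proportional (microfluidic drag) force;
* a **synthetic experiment generator** reproducing the three assay
  geometries (seed-anchored filaments, striped filaments grown under
  alternating conditions, surface-anchored formins under flow) with frame
  quantization, censoring and spurious detachments;
* the complete **measurement pipeline**: survival fractions with right
  censoring, mono-exponential fits with Monte-Carlo-calibrated 65%
  confidence intervals (half-width ≈ k0/√N), local-hazard estimation for
  force ramps, time→force mapping f(t) = κ(L0 + vt), force binning, the
  functional-fraction correction `0.74·k_obs < k_off < k_obs`, and the
  duration-weighted striped-filament deconvolution
  `v = (Δt1·v1 + Δt2·v2)/(Δt1 + Δt2)`.

## Worked example

```python
import numpy as np
from forminproc import (Conditions, ForceProtocol, MDIA1, dissociation_rate,
                        simulate_population, survival_curve, fit_exponential,
                        mean_filament_length)

cond = Conditions(actin=1.0, profilin=5.0)     # µM
pred = dissociation_rate(cond, 0.0, MDIA1)     # f = 0 pN
print(f"v_elong = {pred.v_elong:.2f} subunits/s")
print(f"k_off   = {pred.k_off:.5f} /s")

# a 40-filament seed-anchored experiment, then the paper-style fit
traces = simulate_population(40, MDIA1, cond, ForceProtocol(mode="zero"),
                             horizon=20000.0, seed=7)
times = [t.dissociation_time for t in traces if not t.censored]
cens  = [t.dissociation_time for t in traces if t.censored]
est = fit_exponential(survival_curve(times, cens))
print(f"fitted k_off = {est.k:.5f} /s "
      f"(65% CI {est.ci65_low:.5f}-{est.ci65_high:.5f}, N = {est.n})")
```

prints

```
v_elong = 41.56 subunits/s
k_off   = 0.00080 /s
fitted k_off = 0.00088 /s (65% CI 0.00074-0.00102, N = 40)
```

The model predicts a k_off of 8×10⁻⁴ s⁻¹ for the mDia1-like construct at
1 µM actin + 5 µM profilin (profilin protects: without it k_off is
3.1×10⁻³ s⁻¹ at the same actin), and the simulated 40-filament experiment
recovers it within its calibrated 65% confidence interval. At 2 pN of
tension the same construct dissociates twice as fast
(`dissociation_rate(cond, 2.0, MDIA1).k_off` → 1.65×10⁻³ s⁻¹), and the
mean filament length `v·2.7 nm / k_off` drops accordingly.

A command-line interface wraps the studies:

```sh
forminproc simulate  --construct mDia1 --actin 1 --profilin 5 --n 40 --seed 7 --out run/
forminproc analyze   --events run/events.csv --out run/fit/
forminproc regimes   --figures --out run/regimes/
forminproc recover   --seed 1 --out run/recovery/
forminproc calibrate-ci --n 35 --k0 0.01 --m 10000 --seed 1 --out run/ci/
```

Every run writes a `manifest.json` (package version, seed, parameter
hash) beside its outputs; identical commands give byte-identical numeric
outputs.

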