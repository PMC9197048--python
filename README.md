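# eigamma

Gamma oscillations (~30–80 Hz) in primary visual cortex are strongly induced
by grating stimuli, and they collapse when the stimulus contains a
*discontinuity* — an annular gap, an orientation or phase mismatch, or a
contrast step between the receptive-field center and its surround — even
when firing rates barely change. `eigamma` implements, end to end, the two
halves of that story:

1. **A resonant excitatory–inhibitory (E–I) rate model.** Two coupled
   Wilson–Cowan-type populations with lateral recurrent input folded into
   effective synaptic weights. Near a supercritical Andronov–Hopf
   bifurcation the network sustains a gamma-band limit cycle whose power is
   exquisitely sensitive to the recurrent excitatory weight: a discontinuity,
   modelled as a 10–20 % reduction of `wee`, nearly abolishes the rhythm
   while moving the fixed point (the mean rates) only slightly.
2. **The LFP/spike analysis pipeline** used to quantify such effects in
   recordings: single-taper (Slepian, 0.25 s / 4 Hz) difference spectrograms,
   stimulus-vs-baseline change in power, gamma-band power with per-site max
   normalization, discontinuity-regression slopes, Wilcoxon signed-rank and
   paired-t comparisons, and receptive-field mapping by 2D Gaussian fits to
   9×9 evoked-response grids — exercised on seeded synthetic sessions with
   known ground truth.

It is aimed at computational neuroscientists who want a tested reference
implementation of the model and of the spectral bookkeeping, or a synthetic
test bed for discontinuity-style analyses.

## The model

Population activities E and I evolve as

    tau_x dX/dt = -X + f_x(I_x),            x in {E, I}
    I_e = wee*E - wei*I + iE
    I_i = wie*E - wii*I + iI
    f_x(u) = 1/(1+exp(-m_x(u - theta_x))) - 1/(1+exp(m_x*theta_x))

with effective weights `w_xy = W_xy + W_x*LR` absorbing the lateral
recurrent gains of the orientation hypercolumn. Defaults: `wee=16, wei=26,
wie=20, wii=1, mE=mI=1, thetaE=5, thetaI=20, tauE=20 ms, tauI=10 ms`.
External drives `iE`, `iI` stand for center (contrast-like) and surround
(size-like) stimulation.

## Worked example

```python
import numpy as np
from eigamma import (ModelSpec, ExternalInput,
                     weight_perturbation_experiment)

spec = ModelSpec.default()
op = ExternalInput(iE=3.0, iI=7.5)          # oscillatory operating point
for r in weight_perturbation_experiment(spec, "wee", [1.0, 0.9, 0.8], op):
    m = r.metrics
    print(f"wee x{r.scale}: {m.peak_frequency:5.1f} Hz  "
          f"power {m.peak_power:.2e}  amp {m.amplitude:.4f}  "
          f"fixed-point shift {100*r.fixed_point_shift:.1f}%")
```

prints

```
wee x1.0:  45.7 Hz  power 1.61e-03  amp 0.1176  fixed-point shift 0.0%
wee x0.9:  47.4 Hz  power 5.54e-04  amp 0.0695  fixed-point shift 6.7%
wee x0.8:  46.5 Hz  power 3.95e-19  amp 0.0000  fixed-point shift 13.3%
```

A 10 % cut of the recurrent excitatory weight drops gamma power to ~34 % of
baseline, a 20 % cut abolishes the oscillation outright — yet the steady
state (the mean E/I rates) shifts by only 13 %. That ratio of oscillation
sensitivity to rate sensitivity is the resonance the model exists to
demonstrate.

The same effect propagates through the measurement pipeline on synthetic
LFP sessions:

```python
from eigamma import (SessionConfig, generate_model_driven_session,
                     BandSpec, analyze_session)
cfg = SessionConfig(discontinuity_levels=(0.0, 0.1, 0.2), seed=77)
session = generate_model_driven_session(spec, {0.0: 1.0, 0.1: 0.9, 0.2: 0.8}, cfg)
print(analyze_session(session, BandSpec(35, 65)).normalized_power)
# {0.0: 1.0, 0.1: 0.407..., 0.2: 0.082...}
```

A command-line interface mirrors the library:
`eigamma simulate|sweep|perturb|synth|analyze|rfmap --help`.

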