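# guvfrap

Quantitative analysis of lipid membranes in giant unilamellar vesicles
(GUVs) from confocal fluorescence microscopy, covering two workflows:

1. **Lateral lipid diffusion by FRAP.** A circular spot of radius *w* on the
   membrane is photobleached and the fluorescence recovery of the spot ROI is
   timed as mobile labelled lipids diffuse back in. The measured trace
   *F(t)* is rescaled to the fractional recovery

   f(t) = (F(t) − F(0)) / (F(∞) − F(0)),

   where *F(0)* is the intensity just after bleaching and *F(∞)* the mean of
   the last 8 recovery frames. An exponential y = y₀(1 − exp(−a·t)) is
   fitted, the half-life t₁/₂ = ln 2 / a extracted, and the lateral
   diffusion coefficient computed as

   D = 0.224 · w² / t₁/₂  (µm²/s),

   the dimensionless 0.224 being the half-crossing of the Soumpasis
   uniform-disk recovery f(t) = e^(−2τ/t)[I₀(2τ/t) + I₁(2τ/t)], τ = w²/4D.
   The mobile fraction M = (F(∞) − F(0)) / (F(pre) − F(0)) and four
   quality-control rules (spot small vs. membrane area, short bleach pulse,
   M ≥ 0.75, no vesicle movement) decide inclusion.

2. **Membrane composition from ring intensity.** For binary lipid mixtures
   where one component carries the fluorescent label, each vesicle's
   equatorial-ring mean intensity is regressed (zero intercept) on the
   relative labelled-lipid concentration x ∈ {1, 2, 3}; dividing by the
   fitted slope puts the groups on the expected 1-2-3 scale.

A synthetic-data module generates everything the pipeline consumes — noisy
ROI traces (closed-form or exponential shape), rendered image stacks, a
Brownian-walker simulation of the bleach physics that is independent of the
closed form, composition datasets, and labelled multi-condition cohorts at
the diffusion coefficients reported for electroformed and microfluidic
(octanol-assisted, OLA) GUVs — so every stage is testable without microscope
data.

## Worked example

```python
import numpy as np, guvfrap as g

# simulate one vesicle: D = 1.0 µm²/s, w = 2 µm spot, 8 pre-bleach frames,
# 100 recovery frames at 0.2 s, 5% detector noise
cfg = g.SimConfig(D_true=1.0, sigma_noise=5.0, curve_model="exponential_model", seed=1)
trace = g.generate_trace(cfg)
trace.movement = 0.0                      # vesicle tracked as static
res = g.analyze_trace(trace)
print(f"D = {res.D:.3f} um^2/s, t_half = {res.fit.t_half:.3f} s, "
      f"M = {res.M:.3f}, QC pass = {res.qc.passed}")
```

prints

```
D = 0.961 um^2/s, t_half = 0.932 s, M = 0.937, QC pass = False
```

The estimate recovers the ground truth within noise; the vesicle is
nevertheless excluded because with w = 2 µm and D ≈ 1 µm²/s the recovery
half-life (0.93 s here) is shorter than ten times the 0.1 s bleach pulse — the
pulse rule is deliberately strict at fast diffusion. Cohort means are
computed from all converged fits, with QC verdicts carried alongside.

The same pipeline runs from the shell:

```sh
guvfrap simulate cohort --preset electro_DOPC --preset ola_DOPC --seed 1 --out cohort/
guvfrap analyze-frap --traces cohort/ --out results/
guvfrap report --results results/results.tsv --compare electro_DOPC:ola_DOPC --out report/
```

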