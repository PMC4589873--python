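# polymodal-gate

Quantitative machinery for studying how a peptide toxin hijacks the heat
activation pathway of the polymodal nociceptor channel TRPV1, packaged for
reuse: an equilibrium multi-allosteric gating model plus the
electrophysiology analyses that surround it (Hill dose–response fitting,
two-state binding kinetics, heat-activation threshold detection,
heat-desensitization ratios, single-channel statistics), with seeded
synthetic-data generators standing in for patch-clamp recordings.

It is aimed at ion-channel biophysicists who want to reproduce, probe or
extend the model-based reasoning — in particular the prediction that a toxin
acting *through the heat activation pathway* is selectively silenced by
cooling, while capsaicin activation is not.

## The model

The channel pore undergoes a single closed↔open transition with intrinsic
equilibrium constant *L*₀, allosterically coupled to independent two-state
sensors, one per stimulus pathway:

* capsaicin (ligand): *K* = (*c*/*K*_d)^*n*
* voltage: *K* = exp(*zF*(*V* − *V*₁∕₂)/*RT*)
* heat: *K* = exp(−(Δ*H* − *T*Δ*S*)/*RT*)

Each sensor's active state multiplies the open-pore weight by its coupling
factor *J*; simultaneously active sensor pairs may carry cross-coupling
factors. The open probability is

  *P*ₒ = *Z*_open / (*Z*_closed + *Z*_open),

with *Z* summing Boltzmann weights over every sensor-configuration ×
pore-state combination. With all cross-couplings at 1 (the default,
*J*_CV = *J*_CH = *J*_VH = 1, *J*_C = *J*_H = 800) the partition function
factorizes; the general case is evaluated by state enumeration, and a
brute-force enumeration oracle backs both in the test suite.

A toxin can be attached under four hypotheses — modulating the heat,
capsaicin or voltage sensor, or forming an independent branch with its own
pore coupling — and the package derives the observable that discriminates
them: saturating-toxin and saturating-capsaicin *P*ₒ(*T*) curves and a
selective-cooling-inhibition verdict.

The analysis modules implement the standard pipeline quantities: Hill fits
(response = bottom + (top−bottom)/(1+(EC₅₀/*c*)^*n*_H)), mono-exponential
relaxations with 1/τ_on = *k*_on[*L*] + *k*_off and *K*_d = *k*_off/*k*_on,
two-segment Arrhenius threshold fits (log₁₀ *I* vs 1/*T*), NPo/N open
probabilities from half-amplitude idealization, and unitary conductances
from i–V regressions, with Welch t-tests (significance at *P* < 0.001) for
group contrasts.

## Worked example

```python
from polymodal_gate import gating_model as gm
from polymodal_gate import synthetic_data as syn, dose_response as dr

model = gm.attach_toxin(gm.build_model(gm.default_model_spec()), "heat_branch")
report = gm.predict_cooling_selectivity(model)
print(report.selective_cooling_inhibition)

datasets, _ = syn.gen_dose_response(
    syn.DoseResponseConfig(seed=7, n_datasets=10, noise_sigma=0.10))
fits, s = dr.fit_hill_many(datasets)
print(f"EC50 = {s['ec50_mean']*1e9:.1f} +/- {s['ec50_sem']*1e9:.1f} nM, "
      f"n_H = {s['hill_slope_mean']:.2f} +/- {s['hill_slope_sem']:.2f}")
```

prints

```
True
EC50 = 561.4 +/- 46.8 nM, n_H = 1.14 +/- 0.04
```

The first line is the model's verdict that, with the toxin attached to the
heat pathway, cooling collapses the toxin response (Po 0.014 at 10 °C vs
0.889 at 50 °C) while leaving the capsaicin response intact (0.889 vs
0.9998). The second line shows Hill-parameter recovery: ten noisy synthetic
dose–response datasets generated with EC₅₀ = 521.5 nM and slope 1.17 are
fitted back to 561 ± 47 nM and 1.14 ± 0.04 (mean ± s.e.m.). Attaching
100 nM toxin to the default model lowers its half-activation temperature
from 36.7 °C to 26.1 °C.

Scenario runs, including plots and JSON run reports, are available from the
CLI:

```sh
polymodal-gate run fig3d_cooling_prediction --seed 1 --out out/
polymodal-gate generate temperature_ramp --seed 1 --out out/
polymodal-gate detect-threshold --input out/temperature_ramp_1_ramps.csv
```

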