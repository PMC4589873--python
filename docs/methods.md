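# Methods

## Gating model

The channel is modelled at equilibrium as a central pore transition (C↔O,
constant `L0`) energetically coupled to channel-level two-state sensors.
Pathways are treated as single concerted sensors, not per-subunit units: the
subunit stoichiometry of the underlying conformational machinery is not an
observable of the macroscopic data this package targets, and a channel-level
sensor with an adjustable site count `n_sites` reproduces the same family of
macroscopic curves.

Activation factors:

* ligand sensor: `K = (c / Kd)^n_sites`. At `c = 0` the sensor cannot be
  active; "saturation" (`K → ∞`) drives `Po → J·L0 / (1 + J·L0)`.
* voltage sensor: `K = exp(z·F·(V − V_half) / (R·T))`, `F/RT` evaluated at
  the condition's own temperature.
* thermal sensor: `K = exp(−(ΔH − T·ΔS) / (R·T))`; with `ΔH > 0`, `K` is
  strictly increasing in `T` and equals 1 at `T = ΔH/ΔS`.

Units: concentrations molar, voltages mV, temperatures °C at every
interface (Kelvin only internally), energies kcal/mol with
`R = 1.987e-3 kcal mol⁻¹ K⁻¹`.

When all cross-couplings are 1, `Z_closed/Z_open` factorizes as
`(1/L0)·Π (1+K_p)/(1+J_p·K_p)`, evaluated in log space with an asymptotic
branch for `K > 1e12` so saturating stimuli cannot overflow. With
non-trivial cross-couplings the 2^P sensor configurations are enumerated
with log-sum-exp accumulation. Both paths are checked against a brute-force
enumeration oracle in the tests to 1e-12 relative.

### Default parameterization

All defaults are calibrated (tagged so in the spec metadata), chosen once to
reproduce the macroscopic behaviour of the system:

| parameter | default | rationale |
|---|---|---|
| `L0` | 1e-2 | keeps the saturating-agonist ceiling `J·L0/(1+J·L0) ≈ 0.89` ("near-unity" open probability) and keeps agonist responses from being swamped by direct heat activation at the hot end of a 10–50 °C scan; see the cooling-selectivity criterion below |
| `J_capsaicin`, `J_heat` | 800 | strong pathway–pore coupling |
| cross-couplings | 1 | no direct sensor–sensor interaction assumed |
| `J_voltage` | 1 | the voltage dependence of the data analysed here is not the discriminating observable; overridable |
| capsaicin `Kd` | 2.031 μM | tuned so the decorated model's EC₅₀ at 23 °C, +80 mV equals 213.8 nM |
| `z`, `V_half` | 0.6 e, +120 mV | weak voltage sensor typical of TRP channels |
| heat `ΔH` | 100 kcal/mol | large activation enthalpy of heat gating |
| heat `ΔS` | ΔH / 314.15 K | `K_heat = 1` at 41 °C, the heat-activation midpoint |
| toxin apparent `Kd` | 6.164 μM | with efficacy 2e4, gives a toxin EC₅₀ of 521.5 nM at 23 °C |
| toxin efficacy | 2e4 | bound toxin stabilizes the target sensor's active state by ~5.8 kcal/mol |

The toxin's macroscopic apparent `Kd` in the gating model is deliberately
distinct from the kinetic binding `Kd` (0.52 μM) used by the wash-trace
generator: the former is an allosteric lumped constant tuned to the
dose–response midpoint, the latter is the ratio `koff/kon` of the two-state
binding scheme. A single two-state sensor cannot simultaneously match the
room-temperature potency, the binding affinity and a 6 °C threshold shift
at 100 nM; the dose–response calibration was kept and the threshold shift
is programmed explicitly in the ramp generator (below).

### Toxin attachment

`heat_branch`, `capsaicin_branch` and `voltage_branch` multiply the target
sensor's activation factor by the occupancy factor
`(1 + efficacy·x)/(1 + x)`, `x = (c/Kd)^n` — unity at zero toxin, `efficacy`
at saturation. `independent_branch` adds a toxin ligand sensor with its own
pore coupling (default 800) and unit cross-couplings. Attachment returns a
new immutable model; the original is unchanged.

### Cooling-selectivity criterion

`predict_cooling_selectivity` computes saturating-toxin, saturating-capsaicin
and unstimulated `Po(T)` over 10–50 °C and declares selective cooling
inhibition when all three hold (thresholds configurable):

1. toxin `Po` at the coldest temperature < 10% of its hottest value;
2. capsaicin `Po` at the coldest temperature > 50% of its hottest value;
3. the toxin is actually an agonist: max over the scan of
   (toxin `Po` − baseline `Po`) > 0.1.

Clause 3 exists because an attachment that leaves the toxin inert (e.g. the
capsaicin branch with no capsaicin present, where the ligand activation
factor is zero) produces a "toxin response" identical to the baseline, which
itself collapses when cooled; without the agonism clause such attachments
would trivially satisfy clauses 1–2. With the defaults, only the
heat-branch attachment satisfies all three; capsaicin- and voltage-branch
attachments fail clause 3 (the voltage sensor is pore-decoupled at
`J_V = 1`) and the independent branch fails clause 1 (its activation is
temperature-insensitive).

The choice `L0 = 1e-2` is tied to clause 2: with a much smaller `L0` the
saturating-capsaicin response at 50 °C is dominated by direct heat
activation (`Po → 1`) while the 10 °C response stays at the ~`J·L0` ceiling,
so the capsaicin curve would fail clause 2 under *every* hypothesis and the
criterion would discriminate nothing.

## Hill dose–response

Per-dataset nonlinear least squares (lmfit) of
`bottom + (top−bottom)/(1+(EC50/c)^n_H)` with bottom fixed at 0 and top free
by default (responses are baseline-subtracted currents normalized to a
per-replicate reference). Multi-start initialization: EC₅₀ over five
log-spaced points spanning the tested decades × slope starts {0.5, 1, 2};
lowest χ² wins. Standard errors come from the fit covariance; multiple
datasets are fitted individually and averaged as mean ± s.e.m. (the
alternative — pooling all points into one fit — is not used, matching the
per-cell-then-average reading of the published legends). EC₅₀ comparisons
are Welch t-tests on log₁₀(EC₅₀), since EC₅₀ scatters approximately
log-normally across patches; the significance flag is set at P < 0.001.

## Binding kinetics

Relaxations are fitted as `offset + amplitude·exp(−(t−t0)/τ)`; the fit
window starts two samples after the annotated solution switch because the
generator (like a real perfusion system) has a ~10 ms exchange ramp. A fit
is flagged unidentifiable when the amplitude is below 3× the residual RMS
or the fitted τ exceeds 10× the window (a flat trace drives τ → ∞ with a
compensating amplitude/offset pair). With ≥2 on-step concentrations,
`1/τ_on` is regressed on concentration (statsmodels WLS, unit weights by
default): slope = `kon`, intercept = `koff`. The wash-out estimate
`koff = 1/mean(τ_off)` is the one used for `Kd = koff/kon` (it is the more
directly measured quantity); the regression intercept is retained in the
report. With a single concentration, `kon = (1/τ_on − koff)/[L]`, noted in
the report.

## Heat-activation threshold

Two-segment continuous piecewise-linear fit on Arrhenius axes
(`log₁₀ I` vs `1/T_K`), breakpoint searched exhaustively over interior data
points; segments meet at the breakpoint, making the threshold unique.
Acceptance guards: the two-line fit must halve the single-line SSE, the hot
segment must be steeper, and the slope increase must exceed the leak slope
in magnitude (mild leak curvature alone — an exponential-in-°C leak is not a
straight Arrhenius line — can otherwise mimic a breakpoint). Leak-only
records therefore return an explicit no-threshold result rather than an
exception. Non-positive currents are floored at a configurable epsilon
before the log transform and down-weighted.

Real activation curves bend into a plateau as `Po` saturates, which drags a
single-pass breakpoint off the leak/rise intersection — and asymmetrically
so for a toxin-shifted family, which carries more plateau inside a fixed
ramp window. `detect_threshold` therefore refits by default inside a window
(12 °C below, 7 °C above) around the first-pass threshold; on exactly
piecewise-linear data the refit is a no-op, while on model-generated
families it reduces the paired-shift bias from ≈1.3 °C to ≈0.35 °C.
A fixed-current criterion (`threshold_fixed_current`) is provided as the
alternative threshold definition; the two-line intersection is the default.

Desensitization is quantified per patch as heat-evoked current at 55 °C
divided by the same patch's saturating-capsaicin current; patches with
non-positive capsaicin current are excluded with a note, and two groups are
compared with the same Welch t-test machinery.

## Single-channel analysis

Half-amplitude threshold idealization against a baseline estimated from the
all-points histogram. With `unitary_amplitude="auto"`, both levels come from
a two-Gaussian histogram fit; the histogram is declared unimodal (and an
explicit amplitude demanded) unless two prominent peaks exist whose fitted
means are separated by at least three component widths. The closed level is
the level nearer zero current. Events shorter than the dead time (default
2 sampling intervals) are merged, which can only reduce the event count.
`NPo` is the open-time fraction; `Po = NPo/N`. Unitary conductance is the
slope of an i–V regression in pA/mV (reported in pS), fitted separately for
inward and outward limbs by default because the toxin's permeation effect is
side-specific; per-patch slopes feed the group comparison.

## Synthetic-data generators

Each generator is a pure function of `(config, stream index)`: streams are
spawned as `SeedSequence([seed, index])`, so outputs are byte-reproducible
and adding scenarios never perturbs existing ones. Every output carries a
manifest of its ground-truth parameters; the round-trip tests feed manifests
back through the corresponding analysis.

* **Dose–response**: `Hill(truth) × (1 + σ·N(0,1))`, clipped at 0; default
  8 log-spaced concentrations over 10 nM–10 μM, 3 replicates, σ = 5%
  (recovery protocols use 10%).
* **Wash traces**: exact stepwise relaxation of the two-state occupancy at
  piecewise-constant concentration (rate `kon·c + koff`), scaled to
  `i_max`; 10 ms linear exchange ramps; additive Gaussian noise at 5% of
  the steady-state amplitude; defaults `koff = 0.5 s⁻¹`,
  `kon = koff/0.52 μM`, on-step 1 μM.
* **Temperature ramps**: `leak(T) + channel(T)` with a shallow exponential
  leak and `channel(T) = scale·Po(T)` from a heat-pathway gating spec with
  `L0 = 1e-4` (spontaneous openings negligible, so the heat-evoked current
  emerges from leak near 40 °C as in excised patches — distinct from the
  cooling-selectivity default spec, whose larger `L0` serves the criterion
  above). The toxin condition's channel curve is the control curve
  translated by the programmed shift (`channel(T + 6 °C)`), making the
  programmed control-minus-toxin shift exact by construction and recorded
  in the manifest. Ramp window 16–40 °C: cold enough that the shifted
  family retains a leak segment, hot enough to cover the control rise, and
  short of deep `Po` saturation.
* **Single channel**: continuous-time two-state Markov trajectory with
  exact exponential dwell sampling, rendered at the sampling rate; defaults
  `k_open = 1900 s⁻¹`, `k_close = 100 s⁻¹` (stationary `Po = 0.95`, ~2 kHz
  gating) at 5 kHz sampling with 0.2 pA RMS noise; optional Gaussian
  smoothing approximating a recording filter (off by default; scenario
  configs may enable ~1 kHz). The toxin condition scales inward amplitudes
  by 0.7 (permeation effect). Dwells shorter than 1e-3 sampling intervals
  are refused (aliasing guard).
* **Desensitization patches**: log-normal patch-to-patch scatter around a
  control heat/capsaicin ratio of 1; the toxin-incubated group's heat
  responses are multiplied by the ablation factor (default 0) with a small
  positive noise floor; n = 8 per group by default.

What the generators do *not* emulate: capacity transients, series-resistance
and liquid-junction artifacts, amplifier filter ringing, rundown, multiple
conductance levels and Ca²⁺-dependent desensitization. Passing recovery
tests therefore demonstrates correctness of the estimators under the stated
noise model, not robustness to every pathology of real recordings.

## Problem sizes

Recovery protocols use 10 datasets (Hill), 10 trace sets (kinetics),
20 ramp pairs (threshold shift) and 5 s single-channel records; the full
test suite and the acceptance script each complete in well under a minute.

## Known limitations

* The gating model is an equilibrium description; no kinetic (rate-level)
  solution of the pyramid, and no pH/divalent pathways.
* The mapping between the four attachment hypotheses and any particular
  lettered transition scheme in the literature is not asserted; the enum is
  the interface.
* Biphasic dose–response shapes, multi-exponential kinetics, Q10/ΔH
  extraction from the channel Arrhenius segment and hidden-Markov dwell
  analysis are out of scope.
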