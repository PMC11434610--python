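# thzneuro

A conductance-based cortical neuron model in which high-frequency
terahertz (THz) illumination acts as a multiplicative enhancement of the
K⁺ conductance, together with the electrophysiology analysis chain needed
to quantify its consequences — for computational neuroscientists studying
optical neuromodulation of potassium channels and for anyone who needs a
fully synthetic, ground-truthed test bed for standard ephys analyses.

## What it computes

**Model.** A modified Hodgkin–Huxley membrane
(C = 0.75 µF/cm²):

```
C dv/dt = I_stim − sNa·gNa·m³h·(v − vNa) − sK·gK·n^k·(v − vK) − I_leak
```

A ~36 THz field cannot drive the membrane directly (its period is ~28 fs);
it enters only through its cycle-averaged intensity as linear conductance
scale factors sK = 1 + β_K·I (and sNa = 1 + β_Na·I, with β_Na = 0: the
Na⁺ conductance is field-insensitive). Two ambiguous readings of the K⁺
current (gate exponent n¹ vs n⁴) and the leak term (n-gated vs ohmic)
are both implemented and swept as a 2×2 variant grid.

**Analyses.**

* AP metrics: spike detection, threshold (dv/dt ≥ 20 mV/ms), amplitude,
  FWHM/half-width, RMP, rheobase (30 ms pulse, bisection), F–I curves,
  phase plots.
* Voltage clamp: the Nav/Kv/K-leak step protocols, synthetic channel
  currents with closed-form gate relaxation, I–V extraction (peak or
  steady-state), Boltzmann fits f(V) = 1/(1 + exp(±(V½ − V)/k)) on chord
  conductances, single-exponential τ fits, and the ohmic leak fit
  restricted to steps ≥ −65 mV.
* Unit pipeline: trough-to-peak / half-width features, PYR-vs-INT calls
  (430 µs rule or k-means), ISI histograms with refractory-violation
  counts, and pre/post rate-change calls by Wilcoxon rank-sum on 1 s
  binned counts.
* Synthetic data: dead-time Poisson spike trains, biphasic unit
  waveforms, ground-truthed unit populations with configurable
  decreased/increased/unchanged fractions, and clamp trace sets.

## Worked example

`examples/01_simulate_and_measure.py` simulates the n⁴ gated-leak variant
for 500 ms at 10 µA/cm² with and without a 20% K⁺-conductance
enhancement:

```
sK = 1.0: rest  -68.30 mV | steady rate   75.0 Hz | first-AP FWHM 1.490 ms
sK = 1.2: rest  -69.02 mV | steady rate   70.0 Hz | first-AP FWHM 1.412 ms
```

Enhancing the K⁺ conductance hyperpolarizes the resting potential toward
vK, reduces the steady firing rate, and narrows the action potential —
the three signatures of K⁺-mediated suppression of excitability. The
other examples run the full sK sweep (`02`), the voltage-clamp fit chain
(`03`), and the unit-population classification round trip (`04`); each
prints the numbers it computes and what they mean.

A thin CLI mirrors the library (`thzneuro simulate|rheobase|fi-curve|
analyze-ap|clamp|generate|classify|rate-change|ksweep`), reading YAML/JSON
configs and writing CSV traces and JSON reports with full reproducibility
metadata (package version, resolved config hash, seed).

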