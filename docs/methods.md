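# Methods

## The model

`thzneuro` implements a single-compartment conductance-based cortical
neuron of the Hodgkin–Huxley family in which a high-frequency terahertz
optical field acts purely through the potassium conductance:

```
C dv/dt = I_stim − sNa·gNa·m³h·(v − vNa) − sK·gK·n^k·(v − vK) − I_leak
dy/dt   = α_y(v)·(1 − y) − β_y(v)·y          y = m, n
dh/dt   = (h∞(v) − h)·(α_h(v) + β_h(v))      h∞(v) = 1/(1 + exp((v+60)/6.2))
```

with C = 0.75 µF/cm² and the conventional maximal conductances and
reversal potentials gNa = 120, gK = 36, gL = 0.3 mS/cm², vNa = +50,
vK = −77, vL = −54.4 mV (all configurable). The α/β rate functions for m
and n are the classic squid-axon set; the Na⁺ inactivation gate uses the
sigmoidal steady state above (half-inactivation −60 mV, slope 6.2 mV)
with the classic time constant 1/(α_h + β_h). A configurable voltage
shift of the m/n rate curves is provided (`v_shift`, default 0); with the
modified h gate and the variant grid below, the unshifted rates already
place the resting potential between −77 and −65 mV depending on variant,
so no fixed shift is applied by default.

**Why sK is a plain scale factor.** The ~36 THz field oscillates roughly
ten orders of magnitude faster than the membrane time constant, so it
cannot enter the membrane equation as a drive. It acts only through its
cycle-averaged intensity, which multiplies the channel conductances
linearly: sK = 1 + β_K·I, sNa = 1 + β_Na·I, with β_Na = 0 by default
because the Na⁺ conductance is essentially field-insensitive. Intensity
is model-relative; operating points are defined by model output (the
firing-rate reduction), not by a physical field value.

**Variant grid.** The K⁺ current's activation-gate exponent (n¹ vs the
conventional n⁴) and the leak term (gated, gL·n·(v − vL), vs ohmic,
gL·(v − vL)) are genuinely ambiguous readings of the model the package
reproduces, so both are implemented behind `HHParams.k_gate_exponent`
and `HHParams.leak_gated` and analyses sweep the 2×2 grid rather than
guessing an intent. The literal reading (exponent 1, gated leak) is the
default construction.

**Integration.** Fixed-step 4th-order Runge–Kutta, dt = 0.01 ms by
default, with a compiled kernel (numba) and an identical pure-numpy
fallback; a high-accuracy adaptive mode (`method="adaptive"`, RK45 at
rtol 1e−9) serves as an oracle in tests. Gating variables are clipped to
[0, 1] after each step to keep round-off inside the invariant box; a
non-finite state aborts the run with the divergence time. The initial
state is the resting fixed point: the steady-state I–V relation is
scanned for zero crossings on [−95, −20] mV, each root is refined by
Brent's method, stability is judged from the eigenvalues of the full 4×4
Jacobian, and the most hyperpolarized stable equilibrium is used.

## The conductance sweep and its operating points

The headline experiment (`thzneuro.sweep`, `scripts/acceptance.py`)
sweeps sK over [1.0, 3.0] in steps of 0.01 under a constant
suprathreshold current and measures, per sK, (a) the steady-state firing
rate — spikes after the first 100 ms of a 500 ms run, and (b) the FWHM
of one AP — the first detected AP of the run, a convention that stays
well defined even after tonic firing has ceased. Two operating points
are located by linear interpolation on the grid: the sK where the rate
reaches 30% of control (reporting the FWHM percentage there) and the sK
where the FWHM reaches 95% of control (reporting the rate reduction
there).

The stimulus is 1.5× the tonic-firing threshold of the unscaled control,
found by bisection (the threshold current sustaining ≥ 5 Hz steady
firing in a 500 ms run). Variants with no tonic regime under any
constant current up to 50 µA/cm² are reported as phasic rather than
forced.

**What the sweep actually shows.** The target joint behaviour is a FWHM
of 95% of control together with a ~70% firing-rate reduction. The model
cannot realize it, in any of the four variants, and the package reports
this rather than hiding it:

* Both n¹ variants are purely phasic — the n-gated K⁺ current (and leak)
  is so large at rest that a constant current of any amplitude elicits at
  most a single onset spike. A firing-*rate* modulation is undefined.
* Both n⁴ variants are type-II excitable: as sK grows the steady-state
  rate declines smoothly only to ~75% of control and then jumps
  discontinuously to zero (a hard cessation, the mirror image of the
  model's hard firing onset). A graded 70% reduction does not exist at
  any constant stimulus amplitude; the 30%-of-control level is only
  crossed through the discontinuity, and the interpolated crossing sits
  at the cessation edge.

Consequently the FWHM percentage at the 30%-rate crossing is ≈ 97% (n⁴,
gated leak; ≈ 97.6% for the ohmic-leak variant) — close to the 95%
target — while the rate reduction at the 95%-FWHM crossing is 100%,
far from ~70%, because the FWHM reaches 95% of control just past the
cessation point. A graded coexistence of those two numbers would require
class-I (continuous f–I) dynamics, which this rate-function family does
not produce. The acceptance suite therefore checks that the sweep either
meets the joint tolerance or quantifies the mismatch, and the sweep
output records the best-matching variant, its stimulus, and both
operating points.

## AP metrics

Spike detection: upward crossings of 0 mV followed by a local maximum,
peaks separated by ≥ 2 ms, peak times refined by parabolic
interpolation (so step-halving convergence can be asserted below the
sample interval). AP threshold: first sample of the fast upstroke where
dv/dt ≥ 20 mV/ms (configurable). Width: interpolated duration above the
midpoint between baseline and peak; the default baseline is the
threshold voltage, with an RMP-to-peak alternative. FWHM and
"half-width" are one computation under one convention, recorded in
report metadata. Rheobase: smallest 30 ms pulse amplitude eliciting ≥ 1
spike, by bisection to 0.01 µA/cm², with the simulation extended 20 ms
past the pulse so offset-triggered spikes count.

## Voltage clamp

Step protocols: Nav (hold −100 mV, steps −80…−10 mV), Kv (hold −100 mV,
steps −70…+130 mV, 100 ms), K-leak (hold −70 mV, steps −120…−30 mV,
400 ms); 10 mV increments by default (the increment is a convention, not
a printed value; Nav test-pulse duration is likewise unprinted and
defaults to 25 ms). Synthetic currents come from first-order
Boltzmann-gated kinetics — under a clamp each gate relaxes exponentially,
so traces are closed-form and recovery tests are exact. I–V extraction
uses the signed peak for Nav and the mean over the last 20% of the step
for Kv (the measurement mode is selectable because either reading is
defensible). Boltzmann fits run on chord conductances G = I/(V − E_rev),
are initialized at the voltage nearest half-maximal response with
k₀ = range/6, bounded k ∈ (0.1, 50) mV, and are normalized by the fitted
amplitude rather than the largest data point (robust to noise). The leak
fit is an ordinary least-squares line through the steady-state (V, I)
pairs of the steps at or above −65 mV — exactly four levels under the
default protocol.

## Unit pipeline

The pipeline starts from sorted units (spike sorting is out of scope).
Features: trough-to-peak duration and trough-lobe half-width (at half
trough depth, interpolated), plus mean rate. Classification: putative
pyramidal cell iff trough-to-peak > 430 µs, or k-means with k = 2 on
standardized features (10 restarts, fixed seed), the cluster with the
larger mean trough-to-peak labelled PYR and ties broken by the 430 µs
rule. Rate change: two-sided Wilcoxon rank-sum on 1 s bin counts
(binning and α = 0.05 are conventions; the underlying test is the
documented choice), direction by the sign of the median bin-count
difference, "unchanged" iff p ≥ α.

## Synthetic data

Spike trains are Poisson with a 2 ms dead time (ISI = refractory +
exponential), so the expected count is duration·rate/(1 + rate·refractory).
Waveforms are a negative Gaussian trough lobe plus a smaller (0.4×)
positive Gaussian peak lobe — an artifact template family chosen so
every parameter round-trips through the feature extractor to within one
sample at 30 kHz. Populations draw trough-to-peak from modes at 600 µs
(PYR) and 250 µs (INT), σ = 60 µs each, straddling the 430 µs boundary;
baseline rates are normal with means 5 Hz (PYR) and 10 Hz (INT), floored
at 0.5 Hz. Each unit receives a direction (decreased / increased /
unchanged) with sham fractions (63.4, 10.8, 25.8)% or nerve-injured
("SNI") fractions (61.8, 20.3, 17.9)%, allocated by largest-remainder
proportional assignment and shuffled, so a finite population realizes
the configured fractions as closely as integer counts allow; affected
units multiply their post-epoch rate by 0.5 (decreased) or 1.5
(increased), both conventions since no effect size is documented.
Epochs last 60 s each.

What the generator does **not** emulate: bursting and serial ISI
correlations, rate non-stationarity, waveform drift and sorting errors,
correlated noise across units, and the true (heavier-tailed) rate
distributions of cortical populations. Passing recovery tests therefore
demonstrate that the analysis chain is correct and calibrated on its
stated assumptions, not that it is robust to every pathology of real
recordings.

## Problem sizes and numerical choices

Default runs are sized for a laptop-class single core: 500 ms membrane
simulations at dt = 0.01 ms, a 201-point sK grid per variant (the full
four-variant sweep takes seconds with the compiled kernel), 200
replicates for noisy-fit bias estimates, 1000 synthetic units for
classifier agreement, and 1000/100 runs for the rate-change
type-I/power calibration. Ties in k-means label assignment, fit
initialization rules, and degenerate-input errors (empty traces, windows
outside the data, fewer than two qualifying leak steps) are all fixed
and tested so results are bit-reproducible given a seed.

## Known limitations

* The conductance-scaling law is linear by construction; saturation at
  high intensity is not modelled.
* The neuron is a point model: no morphology, synaptic input, noise, or
  temperature dependence, and no thermal effect of the optical field.
* The joint FWHM/rate operating point discussed above is reported as
  irreproducible under this model family; see the sweep section.
* Clamp synthetics have no series-resistance or capacitive artifacts,
  and gate time constants are voltage-independent.
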