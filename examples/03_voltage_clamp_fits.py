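"""Voltage-clamp analysis: I-V slopes, Boltzmann fits, and the leak rule.

Generates synthetic clamp trace sets for the Kv and K-leak step protocols,
then runs the analysis chain: steady-state I-V extraction, conversion to
chord conductance, Boltzmann fit of the activation curve, and the ohmic
leak fit restricted to steps at or above -65 mV.
"""

from thzneuro import (LeakChannel, fit_boltzmann, iv_curve, kv_channel,
                      leak_analysis)
from thzneuro.clamp import conductance_from_iv
from thzneuro.synth import gen_current_traces

# Kv: delayed-rectifier currents under the -70..+130 mV step protocol
true_v_half, true_k = -10.0, 14.0
traces = gen_current_traces(
    "kv", channel=kv_channel(v_half=true_v_half, k=true_k),
    noise_sigma=2.0, seed=1)
iv = iv_curve(traces, mode="steady-state")
fit = fit_boltzmann(iv.v, conductance_from_iv(iv, e_rev=-77.0), "activation")
print(f"Kv I-V slope (chord over all steps): {iv.slope():.3f} mS/cm^2")
print(f"Boltzmann fit: V1/2 = {fit.v_half:.2f} mV (truth {true_v_half}), "
      f"k = {fit.slope_k:.2f} mV (truth {true_k})")

# K-leak: ohmic currents under the -120..-30 mV protocol; only steps at or
# above -65 mV qualify for the leak fit
leak_traces = gen_current_traces(
    "kleak", channel=LeakChannel(g=0.10, e_rev=-90.0),
    noise_sigma=0.05, seed=2)
leak = leak_analysis(leak_traces, v_min=-65.0)
print(f"\nK-leak fit over steps {leak.levels_used}:")
print(f"  g = {leak.g:.4f} mS/cm^2 (truth 0.10), "
      f"E_rev = {leak.e_rev:.1f} mV (truth -90)")
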