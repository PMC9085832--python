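"""Steady-state activation and kinetics of simulated voltage families.

Generates tail-current recordings from a Boltzmann truth (V½ = −118.5 mV
without cAMP, −100.6 mV with saturating cAMP), fits each recording
individually, and reports the cAMP-induced shift ΔV½.  Also fits a
delayed single exponential to one activation time course.
"""

import numpy as np

from channelrot.ephys import delta_v12, fit_boltzmann, fit_exponential
from channelrot.synthetic import EphysSpec, generate_activation_traces

recs0, traces = generate_activation_traces(
    EphysSpec(V_half=-118.5, noise_sd=0.02, n_recordings=8, seed=11))
recs1, _ = generate_activation_traces(
    EphysSpec(V_half=-100.6, noise_sd=0.02, n_recordings=8, seed=12))

fits0 = [fit_boltzmann(r) for r in recs0]
fits1 = [fit_boltzmann(r) for r in recs1]
shift, sem = delta_v12(fits0, fits1)

print(f"V1/2 (zero cAMP):       {np.mean([f.V_half for f in fits0]):.1f} mV")
print(f"V1/2 (saturating cAMP): {np.mean([f.V_half for f in fits1]):.1f} mV")
print(f"ΔV1/2 = {shift:.1f} ± {sem:.1f} mV  (truth 17.9 mV)")
print(f"effective gating charge zδ ≈ {np.mean([f.z_delta for f in fits0]):.2f}")

tr = traces[("rec000", -150.0)]
ef = fit_exponential(tr["t_ms"].to_numpy(), tr["I"].to_numpy())
print(f"\nactivation kinetics at -150 mV: τ = {ef.tau:.0f} ms "
      f"(fit started at t = {ef.delay:.0f} ms after the initial delay)")
print("The depolarising ΔV1/2 shift is the hallmark of cAMP relieving the")
print("autoinhibition of the intracellular CL-CNBD region.")
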