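"""Gate geometry: opposite Cβ–Cβ distances and gate side-chain mobility.

The toy gate Cβ ring has radius 8 Å, so each opposite pair is 16 Å apart;
with positional noise the per-frame distances scatter around that
diameter.  Side-chain RMSF of the gate residues measures how mobile the
constriction is.
"""

from channelrot.fluctuations import gate_distances, gate_rmsf
from channelrot.synthetic import EnsembleSpec, build_toy_tetramer, generate_rotated_ensemble

start = build_toy_tetramer()
ens = generate_rotated_ensemble(
    start, EnsembleSpec(n_replicas=10, n_frames=40, noise_amplitude=0.2, seed=5))

gm = gate_distances(ens, gate_res_ids=(32, 36, 40))
print("opposite-pair Cβ–Cβ distances (mean ± SEM over 2 pairs × 10 replicas):")
print(gm.distance_summary.to_string(index=False))

tab = gate_rmsf(ens, gate_res_ids=(32, 36, 40))
per_res = tab.table.groupby("res_id")["rmsf"].mean()
print("\ngate side-chain RMSF (Å, mean over subunit × replica):")
print(per_res.to_string())
print("\nDistances near 16 Å show an unchanged pore diameter; the RMSF level")
print("reflects the σ=0.2 Å isotropic noise (expected ≈ σ·√3 = 0.35 Å).")
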