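"""Significance-masked ΔRMSF between two channel states.

Two ensembles share the same per-residue noise amplitudes except for the
elbow residues 60–62, which fluctuate twice as strongly in the 'other'
state.  ΔRMSF = RMSF(reference) − RMSF(other), reset to zero wherever a
per-residue t-test over the subunit × replica values is not significant.
"""

from channelrot.fluctuations import delta_rmsf, rmsf
from channelrot.synthetic import EnsembleSpec, build_toy_tetramer, generate_rotated_ensemble

start = build_toy_tetramer()
base = dict(n_replicas=8, n_frames=40, rotation_sd=0.0, noise_amplitude=0.1)
reference = rmsf(generate_rotated_ensemble(start, EnsembleSpec(seed=3, **base)))
other = rmsf(generate_rotated_ensemble(
    start, EnsembleSpec(seed=4, noise_amplitudes={60: 0.2, 61: 0.2, 62: 0.2},
                        **base)))

delta = delta_rmsf(reference, other, alpha=0.05)
flagged = delta.table[~delta.table["masked"]]
print(flagged.to_string(index=False))
print(f"\n{len(flagged)} of {len(delta.table)} residues significant at α=0.05.")
print("Negative ΔRMSF: the residue is MORE mobile in the other state —")
print("exactly the doubled-amplitude elbow residues the generator planted.")
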