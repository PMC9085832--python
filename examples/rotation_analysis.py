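"""Measure the CL-CNBD rotation of two simulated channel states.

Builds the miniature C4 tetramer, generates an apo-wild-type-like ensemble
(rotation ~N(3.45°, 1°)) and a K464E-variant-like ensemble (~N(0.52°, 1°)),
and measures the signed rotation of the intracellular block about the pore
axis with the four-point dihedral built on centre-of-mass reference points.
"""

from channelrot import rotation as rot
from channelrot.ensemble_stats import two_sample_ttest
from channelrot.synthetic import EnsembleSpec, build_toy_tetramer, generate_rotated_ensemble

start = build_toy_tetramer()
ref = rot.build_rotation_reference(
    start, elbow_res=(60, 61, 62, 63), pore_res_upper=36, pore_res_lower=32,
    pore_span=tuple(range(28, 45)),
)

common = dict(n_replicas=10, n_frames=50, rotation_sd=1.0, noise_amplitude=0.05)
apo = rot.rotation_summary(
    generate_rotated_ensemble(start, EnsembleSpec(rotation_mean=3.45, seed=1, **common)),
    ref,
)
var = rot.rotation_summary(
    generate_rotated_ensemble(start, EnsembleSpec(rotation_mean=0.52, seed=2, **common)),
    ref,
)
test = two_sample_ttest(
    apo.per_subunit_replica["angle_deg"].to_numpy(),
    var.per_subunit_replica["angle_deg"].to_numpy(),
)

print(f"apo-like rotation:     {apo.mean:+.2f} ± {apo.sem:.2f} deg (n={apo.n})")
print(f"variant-like rotation: {var.mean:+.2f} ± {var.sem:.2f} deg (n={var.n})")
print(f"difference:            {apo.mean - var.mean:.2f} deg, t-test p={test.p_value:.2g}")
print("A positive angle is a rotation in the direction the apo wild-type")
print("channel relaxes; the ~2.9 deg gap is the variant's displaced pose.")
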