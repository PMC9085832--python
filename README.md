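# channelrot

Quantitative analysis of opposite-subunit coupling in tetrameric HCN
pacemaker channels: inter-subunit hydrogen-bond/salt-bridge occurrence
frequencies, the rotation of the intracellular C-linker/CNBD (CL-CNBD)
block about the pore axis, significance-masked residue mobility changes
(ΔRMSF), gate geometry metrics, and the fitting stack for
electrophysiology and confocal patch-clamp fluorometry (cPCF) recordings.

It is written for structural biologists and channel physiologists who
post-process MD ensembles of C4-symmetric channels (multi-model PDB, one
file per replica) and tabular patch-clamp/cPCF data, and want the whole
analysis — from contact detection to the significance report — as a
tested, scriptable Python library.

## The quantities it computes

**Contact occurrence frequency.** A hydrogen bond between a donor heavy
atom D (with hydrogens H) and an acceptor A is counted in a frame when
d(D, A) ≤ 3.5 Å and the angle ∠(D, H, A) ≥ 120°; salt bridges use the same
criteria on side-chain N donors and carboxylate O acceptors. The
occurrence frequency is the fraction of frames in which any
donor/hydrogen/acceptor combination passes, scored for all four symmetric
placements (donor subunit *i* against acceptor subunit *i*+2 or *i*+1),
giving n = 4 subunits × replicas values summarised as mean ± SEM.

**CL-CNBD rotation.** After least-squares (Kabsch) superposition of the
pore onto the starting structure, the signed dihedral I–II–III–IV is
measured per subunit, where I is the static per-subunit centroid of the
Cα atoms of the C-linker elbow terminal residues (M460–H463 in mHCN2),
II and III are static centroids of the Cα atoms of T436 and I432 over all
four subunits (on the pore axis by symmetry), and IV is the current-frame
elbow centroid. Per-frame angles are averaged per (subunit, replica) and
reported as grand mean ± SEM (n = 80 for 20 replicas).

**ΔRMSF.** Residue-wise RMSF over all non-hydrogen side-chain atoms,
per replica after alignment onto the replica-average structure;
ΔRMSF = RMSF(reference state) − RMSF(other state), reset to zero for
residues whose two-sample t-test over the subunit × replica values gives
p ≥ 0.05.

**Gate metrics.** Cβ–Cβ distances between opposite gate residues
(I432, T436, Q440 in mHCN2; two pairs per residue per frame, n = 40 for
20 replicas) and gate side-chain RMSF.

**Recording fits.** Steady-state activation
I/Imax = a/[1 + exp(zδ·F·(V − V½)/RT)] per recording; activation and
deactivation time courses as a single exponential after an initial delay;
concentration–binding as the Hill relation
F/Fmax = 1/[1 + (BC50/[agonist])^H] fitted to averaged data; cPCF
background subtraction by scaling the reference-dye channel onto the
ligand channel over bath and pipette, subtracting, and quantifying the
bound fraction in the patch dome only.

A synthetic-data module generates every input class with known ground
truth — a miniature C4-symmetric tetramer, rotated/noisy ensembles,
Bernoulli contact trajectories, Boltzmann/exponential/Hill-governed
recordings and two-channel cPCF images — so each analysis stage has a
closure test `analyse(generate(truth)) ≈ truth`.

## Worked example

```bash
python examples/rotation_analysis.py
```

```
apo-like rotation:     +3.43 ± 0.02 deg (n=40)
variant-like rotation: +0.56 ± 0.02 deg (n=40)
difference:            2.87 deg, t-test p=6.2e-80
```

Two ensembles are generated with true per-frame rotations N(3.45°, 1°)
and N(0.52°, 1°) — the apo wild-type and K464E-variant levels — and the
dihedral metric recovers both grand means and their ~2.9° separation,
which the t-test over the subunit × replica values declares significant.
The other scripts in `examples/` walk through contact occupancy, ΔRMSF,
gate geometry, activation fitting (ΔV½ = 17.8 ± 0.2 mV recovered from a
17.9 mV truth) and binding/cPCF analysis (BC50 = 0.40 µM, H = 1.47 from a
0.40 µM/1.5 truth) the same way.

A thin CLI wraps the same library calls:

```bash
channelrot simulate --kind contacts --seed 3 --out sim/
channelrot contacts --ensemble sim/contacts.pdb \
    --donor 64:sidechain-N --acceptor 5:backbone-O --role opposite
channelrot run --config run.json   # full multi-state comparison
```

## Layout

- `src/channelrot/model_io.py` — ensemble/topology types, multi-model PDB I/O, selections
- `src/channelrot/interactions.py` — H-bond/salt-bridge detection and frequencies
- `src/channelrot/rotation.py` — superposition, reference points, rotation dihedral
- `src/channelrot/fluctuations.py` — RMSF, ΔRMSF, gate metrics
- `src/channelrot/ensemble_stats.py` — SEM aggregation and t-tests
- `src/channelrot/ephys.py` — Boltzmann/exponential/Hill fits, cPCF subtraction
- `src/channelrot/synthetic.py` — ground-truth generators
- `src/channelrot/pipeline.py`, `cli.py` — orchestration and the `channelrot` command
- `docs/methods.md` — models, assumptions, numerical choices, limitations
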