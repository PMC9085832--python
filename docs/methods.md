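# Methods

## Scope and data model

The package analyses ensembles of a homotetrameric ion channel stored as
multi-model PDB files, one file per independent MD replica and one MODEL
per stored frame. Subunits are identified by chain ID through an explicit
map (default A–D → 0–3); the only symmetry relation the analyses rely on
is that the diagonal ("opposite") partner of subunit *i* is (*i*+2) mod 4
and the adjacent partner (*i*+1) mod 4, so the unknown correspondence
between chain labels and any published figure panel is immaterial. Frames
carry no absolute time: no analysis here uses time units, so frame
spacing is treated as metadata. Coordinates are always Ångström, and the
round-trip guarantee through the PDB writer is the format's three
decimals.

Residue numbering follows mHCN2 (UniProt O88703) for real data. The
built-in miniature test system uses a documented mapping: HCN-domain
residues are the mHCN2 number − 150 (site 5 ↔ M155) and pore/C-linker
residues the number − 400 (gate 32/36/40 ↔ I432/T436/Q440, elbow
60–63 ↔ M460–H463, donor 64 ↔ K464).

## Contact detection

A hydrogen bond is scored per frame from the heavy-atom donor–acceptor
distance (cutoff 3.5 Å) and the donor–H–acceptor angle with vertex at the
hydrogen (cutoff 120°). Hydrogens are attached to a donor by PDB naming
convention first (remoteness suffix, e.g. HZ1/HZ2/HZ3 on NZ), with a
geometric fallback (any same-residue hydrogen within 1.2 Å). Degenerate
geometry — a hydrogen coincident with the donor — leaves the angle
undefined and fails the criterion; this is logged once. Models without
hydrogens fall back to a distance-only mode, flagged in the result.

Salt bridges reuse the same criteria on the charged groups (side-chain N
donors of Lys/Arg/His, side-chain O acceptors of Asp/Glu), consistent
with analysing both interaction types through one trajectory tool;
whether the original analysis included the angle term for salt bridges is
not documented, so the distance-only mode is available and labelled.

A frame counts as bonded when *any* donor-atom/hydrogen/acceptor-atom
triple passes ("any combination" semantics), which matches residue-level
occupancy reporting. All four symmetric placements of a contact are
scored, so an ensemble of R replicas yields n = 4R per-(pair, replica)
fractions, summarised as mean ± SEM.

## Rotation metric

The rotation of the intracellular CL-CNBD block is measured as the signed
four-point dihedral I–II–III–IV:

- **I** (static, per subunit): centroid of the Cα atoms of the C-linker
  elbow terminal residues, from the starting structure. Keeping I
  per-subunit is forced by the physics: a C4-symmetric rotation would
  cancel in any pooled reference.
- **II**, **III** (static, shared): centroids of the Cα atoms of the
  upper and lower pore marker residues over all four subunits. By C4
  symmetry they lie on the pore axis, so the II–III segment *is* the
  axis.
- **IV** (dynamic): the elbow centroid of the current frame.

Centroids are unweighted Cα means — mass weighting over four identical
selections changes nothing material. Before measuring, each frame is
rigid-body superimposed (rotation + translation, no scaling or
reflection; SVD/Kabsch with determinant correction) onto the starting
structure over the pore Cα selection (default mHCN2 428–444, all
subunits, configurable; the choice of S6 gate-region span is this
package's own, as only "the pore" is prescribed). The dihedral uses the
atan2 formulation for stability near 0°/180° and returns angles in
(−180°, 180°].

Sign convention: positive angles are the direction the apo wild-type
channel rotates away from the starting structure, which for the toy
system coincides with a positive (counter-clockwise viewed from +z)
rotation about the pore axis; a `sign_convention` multiplier flips it if
a different viewing convention is wanted. Per-frame angles are averaged
within each (subunit, replica) and reported as grand mean ± SEM over
those n values. Which reference structure differences are reported
against (starting structure or another state's average) is left to the
caller: `rotation_summary` always measures against the reference it is
given.

Average structures are coordinate-wise means after superimposing every
frame on the first frame's pore selection (`align=False` for pre-aligned
frames).

## RMSF and ΔRMSF

Per replica, frames are aligned onto the replica-average structure over a
caller-supplied selection (the pore Cα set in the pipeline; one alignment
pass to the first frame, averaging, then re-alignment to that average).
Whether the original analysis used per-replica or pooled mean reference
positions is unstated; per-replica is primary here because it is the
variant consistent with treating the n = subunits × replicas values as
independent. Per atom, RMSF = √⟨|x − ⟨x⟩|²⟩ over the replica's frames;
per residue, the unweighted mean over the residue's selected atoms
(robust to side-chain size; a pooled-RMS mode is switchable). Glycine and
other residues with no selected atoms are omitted and logged, not
zero-filled.

ΔRMSF between a reference and another state is the difference of the
per-residue means, reset to zero wherever a two-tailed two-sample t-test
over the residue's subunit × replica samples gives p ≥ α (default 0.05).
Welch's variant is the default (unequal variances are the norm for RMSF);
the pooled-variance Student test is available. No multiple-testing
correction is applied, matching per-residue raw-p masking; the null
calibration (≈ 1 − α of residues masked on same-model ensembles) is a
tested property.

The study design treats the four subunits of one trajectory as
independent (n = 80 for 20 replicas). The stats module reproduces this
but also offers a per-replica-collapsed summary (n = 20) so the
pseudo-replication choice stays visible. Two zero-variance samples with
equal means give p = 1 by convention.

## Gate metrics

Per gate residue, the Cβ–Cβ distance between the two opposite pairs
(0,2) and (1,3) per frame; per-replica means are aggregated to
mean ± SEM with n = 2 pairs × replicas. Gate side-chain RMSF is the RMSF
machinery restricted to the gate residues.

## Recording fits

- **Boltzmann** (steady-state activation): I/Imax =
  a/[1 + exp(zδ·F·(V − V½)/RT)], unweighted nonlinear least squares per
  recording after normalising tail amplitudes to the recording maximum
  (inward currents by |max|, preserving monotonicity). zδ is kept
  positive with the sign structure as written, so activation grows toward
  hyperpolarised voltages. The recording temperature is not part of the
  data and defaults to 293.15 K (room-temperature oocyte recordings);
  zδ scales inversely with T, so the value used is logged with every fit.
  Parameters are averaged across recordings afterwards; ΔV½ is the
  difference of group means with SEM propagated in quadrature
  (independent patches; a paired mode would need patch identity, which
  the tables do not carry).
- **Exponential** (activation/deactivation kinetics): a single
  exponential starting after an initial delay. The implementation fits
  I(t) = C + A·exp(−(t − delay)/τ) so rising activation and decaying
  deactivation both reduce to the same engine; C = 0 recovers the bare
  printed form. The auto-delay policy places the fit start at the first
  time the signal crosses 10% of its final span (a fixed-delay mode is
  available). That start lands slightly after the true lag — by
  τ·ln(10/9) ≈ 0.105 τ for an ideal rise — but τ is unaffected because
  the amplitude refits; the tests pin both facts.
- **Hill** (concentration–binding): F/Fmax = 1/[1 + (BC50/c)^H] fitted to
  *averaged* data (the one fit done on pooled rather than per-recording
  data, matching how cPCF patches are pooled), amplitude fixed at 1 by
  default since F is already normalised to the saturating concentration.
- **cPCF subtraction**: scale s = mean(green)/mean(red) over
  bath ∪ pipette (free dye only), corrected = green − s·red, bound
  fraction = mean(corrected over dome)/Fmax. The result is invariant to
  rescaling the red channel and to adding any multiple of red to green;
  small negative values at zero binding are reported as computed, with a
  log note.

All least squares are unweighted (no weighting scheme is prescribed by
the data); a robust-loss option is deliberately absent.

## Synthetic data

The generators define the conditions under which everything is tested:

- **Toy tetramer**: ~40 residues per subunit (analysis code is
  size-agnostic; tests must run in seconds), exactly C4-symmetric, with a
  gate Cβ ring of radius 8 Å (opposite distance 16 Å), a C-linker elbow
  at radius 18 Å, a lysine-like donor whose NZ sits 2.9 Å / 170° from the
  opposite subunit's site backbone O, hydrogens on the donor, and one
  glycine to exercise the empty-side-chain path. Overlapping heavy atoms
  (< 0.4 Å between residues) abort construction.
- **Rotated ensembles**: per frame and per subunit an angle
  θ ~ N(mean, σ) is drawn independently and the CL block rotated about
  the pore (z) axis; every atom then receives isotropic Gaussian noise
  with its residue's amplitude (default 0.1 Å, per-residue overrides).
  Independent per-subunit draws are what make the n = subunits × replicas
  bookkeeping statistically meaningful in recovery tests. The noise model
  has no covariance structure — a deliberate simplification of MD
  dynamics, sufficient for RMSF/rotation closure but not a model of
  correlated domain motions, solvent drag or force-field physics.
- **Contact trajectories**: per frame and directed pair, a Bernoulli(p)
  draw keeps the acceptor site in its starting contact geometry or
  displaces it along the donor→acceptor direction to 6 Å; draws are
  recorded as ground truth.
- **Recordings**: tail amplitudes from the Boltzmann curve over voltage
  families −150…−70 mV in 10 mV steps with Gaussian noise (σ = 0.02 on
  the relative amplitude, the visual scatter of clean oocyte
  recordings); time courses as delayed rising exponentials with
  τ(V) = τ_ref·exp((V − V_min)/40 mV); binding tables as Hill responses
  averaged over patches; cPCF image pairs with a uniform free-dye red
  channel and a dome-only bound component.

Every generator is bit-reproducible given (spec, seed); replicas use
independently spawned RNG streams so they are independent yet
reproducible. What passing tests show is that the *estimators* are
correct and calibrated under these idealised conditions; they do not show
that real MD trajectories satisfy the noise model, and headline values
from the original study (20 × 1 µs all-atom simulations, oocyte
recordings) are used here as generator ground truths for recovery
testing, not re-derived from physics.

## Numerical choices and problem sizes

Superposition rejects selections with fewer than three or collinear
atoms; the dihedral rejects points on the central axis. Fits start from
data-driven initial guesses (median-crossing interpolation) and raise a
fit error with context on non-convergence rather than returning garbage.
The default test suite and the acceptance script use toy problem sizes —
up to 20 replicas × 100 frames for rotation recovery, 2000 frames for
RMSF/occupancy closure, ≤ 100 recordings per fit-recovery check — chosen
so the whole suite completes in well under a minute while keeping the
statistical tolerances (3 SEM, binomial 99% intervals, 2–5% relative
error) meaningful.

## Known limitations

- No mmCIF or binary trajectory formats (DCD/XTC); convert upstream.
- Topology is taken from atom records; bonds are never perceived
  (hydrogen attachment is name/distance-based).
- π-stacking, cation-π and water-mediated bridges are out of scope.
- Leak subtraction, capacitance/series-resistance compensation, rundown
  modelling and image registration are assumed done upstream; cPCF ROIs
  are inputs, not segmented.
- The t-tests inherit the study's independence assumption across subunits
  of one trajectory; use the per-replica-collapsed summaries when that
  assumption is in doubt.
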