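"""Generators for every input class with known ground truth.

The analyses in this package were designed for ensembles of a tetrameric
HCN pacemaker channel; this module builds miniature stand-ins with the
same topology so each analysis stage has a closure test
``analyse(generate(truth)) ≈ truth`` that runs in seconds:

* a C4-symmetric toy tetramer whose arms carry the features the analyses
  touch — a pore helix with gate residues, a C-linker elbow, a lysine-like
  donor, and an HCN-domain acceptor site on the *opposite* subunit;
* ensembles in which the intracellular (CL-CNBD) block of every subunit
  is rotated about the pore axis by angles drawn from a prescribed normal
  distribution, plus per-residue harmonic positional noise;
* frame sequences in which the donor/acceptor pair occupies contact
  geometry with a prescribed Bernoulli probability;
* Boltzmann-governed tail currents, delayed-exponential time courses,
  Hill-governed binding data and two-channel cPCF images with a known
  bound fraction.

Toy residue numbering (miniature ↔ mHCN2): HCN-domain residues are the
real number − 150 (site 5 ↔ M155); pore/C-linker residues are the real
number − 400 (gate 32/36/40 ↔ I432/T436/Q440, elbow 60–63 ↔ M460–H463,
donor 64 ↔ K464).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ephys import ActivationRecording, CPCFMeasurement, boltzmann, hill
from .model_io import AtomRecord, Ensemble, Frame, Topology

__all__ = [
    "ToyTetramerSpec",
    "EnsembleSpec",
    "EphysSpec",
    "TOY_RESIDUE_MAP",
    "build_toy_tetramer",
    "generate_rotated_ensemble",
    "generate_contact_trajectory",
    "generate_activation_traces",
    "generate_binding_data",
    "generate_cpcf_images",
]

#: miniature residue id -> mHCN2 residue it stands in for
TOY_RESIDUE_MAP = {
    5: 155,  # HCN-domain acceptor site (M155)
    32: 432, 36: 436, 40: 440,  # gate residues
    60: 460, 61: 461, 62: 462, 63: 463,  # C-linker elbow (A'-helix tip)
    64: 464,  # donor lysine
}


@dataclass(frozen=True)
class ToyTetramerSpec:
    """Geometry of the miniature C4-symmetric tetramer."""

    residues_per_arm: int = 40
    pore_radius: float = 8.0  # Å; gate Cβ ring radius
    elbow_radius: float = 18.0  # Å
    contact_distance: float = 2.9  # Å, donor N – acceptor O in the start
    hcn_site_offset: float = 0.0  # deg, azimuthal offset of the acceptor site
    gate_res_ids: tuple[int, ...] = (32, 36, 40)
    elbow_res_ids: tuple[int, ...] = (60, 61, 62, 63)
    donor_res_id: int = 64
    site_res_id: int = 5
    seed: int = 0

    @property
    def pore_res_ids(self) -> tuple[int, ...]:
        n_pore = self.residues_per_arm - 20
        if n_pore < 13:
            raise ValueError("residues_per_arm must be >= 33")
        return tuple(range(28, 28 + n_pore))


@dataclass(frozen=True)
class EnsembleSpec:
    """Conditions for a generated ensemble of the toy tetramer."""

    n_replicas: int = 20
    n_frames: int = 100
    rotation_mean: float = 0.0  # deg
    rotation_sd: float = 1.0  # deg
    noise_amplitude: float = 0.1  # Å, default per-residue isotropic sd
    noise_amplitudes: dict = field(default_factory=dict)  # res_id -> Å override
    contact_probability: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class EphysSpec:
    """Ground truth for synthetic patch-clamp / cPCF data."""

    V_half: float = -100.6  # mV
    z_delta: float = 4.0
    amp_satV: float = 1.0
    voltages: tuple[float, ...] = tuple(range(-150, -60, 10))
    tau_ref: float = 100.0  # ms at the most hyperpolarised voltage
    delay: float = 20.0  # ms
    noise_sd: float = 0.02  # on relative tail amplitudes
    trace_noise_sd: float = 0.0  # fraction of amplitude, on time courses
    n_recordings: int = 10
    BC50: float = 0.40  # µM
    H: float = 1.5
    concentrations: tuple[float, ...] = (0.05, 0.1, 0.25, 0.5, 1.0, 2.5)
    n_patches: int = 5
    seed: int = 0


# ---------------------------------------------------------------------------
# toy tetramer construction
# ---------------------------------------------------------------------------


def _cyl(radius: float, azimuth_deg: float, z: float) -> np.ndarray:
    a = math.radians(azimuth_deg)
    return np.array([radius * math.cos(a), radius * math.sin(a), z])


_INTRACELL_Z = -34.0  # z level of the elbow / donor / HCN-site layer


def _donor_tip(spec: ToyTetramerSpec, phi: float) -> tuple[np.ndarray, np.ndarray]:
    """NZ position and outward unit vector of the donor on azimuth ``phi``."""
    nz = _cyl(spec.elbow_radius + 4.0, phi + 12.0, _INTRACELL_Z)
    u = np.array([math.cos(math.radians(phi + 12.0)),
                  math.sin(math.radians(phi + 12.0)), 0.0])
    return nz, u


def _acceptor_O(spec: ToyTetramerSpec, phi_site_owner: float) -> np.ndarray:
    """Backbone-O position of the site residue owned by the subunit at
    azimuth ``phi_site_owner``; placed in contact geometry (distance
    ``contact_distance``, donor–H–acceptor angle 170°) with the donor of
    the *opposite* subunit (azimuth + 180°)."""
    nz, u = _donor_tip(spec, phi_site_owner + 180.0)
    h = nz + u  # HZ1, 1.0 Å along the outward direction
    # perpendicular in the horizontal plane
    w = np.array([-u[1], u[0], 0.0])
    psi = math.radians(170.0)
    d_c = spec.contact_distance
    # law of cosines: |DA|^2 = 1 + t^2 - 2 t cos(psi), solve for t = |HA|
    b = -2.0 * math.cos(psi)
    t = (-b + math.sqrt(b * b - 4.0 * (1.0 - d_c * d_c))) / 2.0
    v = math.cos(math.pi - psi) * u + math.sin(math.pi - psi) * w
    return h + t * v


def _residue_atoms(
    res_id: int,
    res_name: str,
    subunit: int,
    ca: np.ndarray,
    axis: np.ndarray,
    names: tuple[str, ...],
) -> list[tuple[AtomRecord, np.ndarray]]:
    """Lay out a residue's atoms around a Cα position along a local axis."""
    offsets = {
        "N": -1.45 * axis + np.array([0.0, 0.0, 0.4]),
        "CA": np.zeros(3),
        "C": 1.52 * axis + np.array([0.0, 0.0, 0.3]),
        "O": 1.52 * axis + np.array([0.0, 0.0, 1.5]),
        "CB": np.array([0.0, 0.0, -1.2]) - 0.8 * axis,
        "CG": np.array([0.0, 0.0, -2.4]) - 1.0 * axis,
    }
    out = []
    for name in names:
        elem = "H" if name.startswith("H") else name[0]
        is_h, is_bb = _flags(name, elem)
        rec = AtomRecord(0, name, elem, res_name, res_id, subunit, is_h, is_bb)
        out.append((rec, ca + offsets[name]))
    return out


def _flags(name: str, elem: str) -> tuple[bool, bool]:
    is_h = elem == "H"
    is_bb = name in {"N", "CA", "C", "O"}
    return is_h, is_bb


def build_toy_tetramer(spec: ToyTetramerSpec = ToyTetramerSpec()) -> Ensemble:
    """Build the one-frame starting structure of the toy tetramer.

    Deterministic given the spec.  The pore axis is the global z axis;
    subunit ``s`` occupies azimuth ``90·s`` degrees.  The gate Cβ ring has
    radius ``pore_radius`` exactly, so opposite gate Cβ atoms are
    ``2·pore_radius`` apart; the donor's side-chain N sits at
    ``contact_distance`` from the opposite subunit's site backbone O.
    """
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []

    def add(rec: AtomRecord, xyz: np.ndarray) -> None:
        atoms.append(rec)
        coords.append(xyz)

    pore_res = spec.pore_res_ids
    for s in range(4):
        phi = 90.0 * s
        radial = np.array([math.cos(math.radians(phi)),
                           math.sin(math.radians(phi)), 0.0])

        # --- HCN-domain residues 1..4 (filler) and 5 (acceptor site) -----
        o_pos = _acceptor_O(spec, phi + spec.hcn_site_offset)
        # local outward basis at the site (rotates with the subunit)
        _, u_site = _donor_tip(spec, phi + spec.hcn_site_offset + 180.0)
        for rid in range(1, 5):
            ca = o_pos + 2.0 * u_site + np.array([0.0, 0.0, -1.8 * (5 - rid)])
            for rec, xyz in _residue_atoms(rid, "ALA", s, ca, u_site,
                                           ("N", "CA", "C", "O", "CB")):
                add(rec, xyz)
        for name, off in (
            ("N", -1.2 * u_site + np.array([0.0, 0.0, -2.4])),
            ("CA", np.array([0.0, 0.0, -1.8])),
            ("C", np.array([0.0, 0.0, -0.7])),
            ("O", np.zeros(3)),
            ("CB", 1.3 * u_site + np.array([0.0, 0.0, -2.4])),
        ):
            is_h, is_bb = _flags(name, name[0])
            add(AtomRecord(0, name, name[0], "MET", 5, s, is_h, is_bb),
                o_pos + off)

        # --- pore helix (TM) ---------------------------------------------
        z_top = 12.0
        for k, rid in enumerate(pore_res):
            twist = 10.0 * k
            z = z_top - 1.5 * k
            cb = _cyl(spec.pore_radius, phi + twist, z)
            ca = _cyl(spec.pore_radius + 1.5, phi + twist, z + 0.4)
            inward = -np.array([math.cos(math.radians(phi + twist)),
                                math.sin(math.radians(phi + twist)), 0.0])
            for name, xyz in (
                ("N", ca + np.array([0.0, 0.0, 0.9]) - 0.5 * inward),
                ("CA", ca),
                ("C", ca + np.array([0.0, 0.0, -0.9]) + 0.3 * inward),
                ("O", ca + np.array([0.0, 0.0, -1.6]) + 0.8 * inward),
                ("CB", cb),
            ):
                is_h, is_bb = _flags(name, name[0])
                add(AtomRecord(0, name, name[0], "LEU", rid, s, is_h, is_bb), xyz)

        # --- C-linker descent: res 50 (GLY) + 51..59 (ALA) ----------------
        z_bot = z_top - 1.5 * (len(pore_res) - 1)
        cl_ca = []
        for j in range(10):
            frac = (j + 1) / 11.0
            r = spec.pore_radius + frac * (spec.elbow_radius - spec.pore_radius)
            z = z_bot + frac * (_INTRACELL_Z + 2.0 - z_bot)
            cl_ca.append(_cyl(r, phi + 0.5 * j, z))
        for j, rid in enumerate(range(50, 60)):
            nxt = cl_ca[min(j + 1, 9)]
            prv = cl_ca[max(j - 1, 0)]
            t_vec = (nxt - prv) / (2.0 if 0 < j < 9 else 1.0)
            t_hat = t_vec / np.linalg.norm(t_vec)
            n_hat = radial - (radial @ t_hat) * t_hat
            n_hat = n_hat / np.linalg.norm(n_hat)
            ca = cl_ca[j]
            offs = {
                "N": -0.33 * t_vec + 0.5 * n_hat,
                "CA": np.zeros(3),
                "C": 0.33 * t_vec + 0.5 * n_hat,
                "O": 0.33 * t_vec + 1.8 * n_hat,
                "CB": -1.4 * n_hat,
            }
            names = ("N", "CA", "C", "O") if rid == 50 else ("N", "CA", "C", "O", "CB")
            res_name = "GLY" if rid == 50 else "ALA"
            for name in names:
                is_h, is_bb = _flags(name, name[0])
                add(AtomRecord(0, name, name[0], res_name, rid, s, is_h, is_bb),
                    ca + offs[name])

        # --- elbow terminal residues (A'-helix tip analogue) ---------------
        for j, rid in enumerate(spec.elbow_res_ids):
            ca = _cyl(spec.elbow_radius, phi - 7.5 + 5.0 * j, _INTRACELL_Z)
            for rec, xyz in _residue_atoms(rid, "ALA", s, ca, radial,
                                           ("N", "CA", "C", "O", "CB")):
                add(rec, xyz)

        # --- donor lysine ---------------------------------------------------
        nz, u = _donor_tip(spec, phi)
        ca = nz - 4.0 * u
        side = {"CB": ca + 1.0 * u, "CG": ca + 2.0 * u, "CD": ca + 3.0 * u,
                "CE": ca + 3.6 * u + np.array([0.0, 0.0, 0.3]), "NZ": nz,
                "HZ1": nz + u,
                "HZ2": nz + np.array([0.0, 0.0, 1.0]),
                "HZ3": nz - np.array([-u[1], u[0], 0.0])}
        for name, xyz in (("N", ca - 1.4 * u + np.array([0.0, 0.0, 0.4])),
                          ("CA", ca),
                          ("C", ca - 0.4 * u + np.array([0.0, 0.0, -1.3])),
                          ("O", ca - 0.4 * u + np.array([0.0, 0.0, -2.5])),
                          *side.items()):
            elem = "H" if name.startswith("H") else name[0]
            is_h, is_bb = _flags(name, elem)
            add(AtomRecord(0, name, elem, "LYS", spec.donor_res_id, s, is_h, is_bb),
                xyz)

    # renumber serials in construction order
    atoms = [AtomRecord(i + 1, a.name, a.element, a.res_name, a.res_id,
                        a.subunit, a.is_hydrogen, a.is_backbone)
             for i, a in enumerate(atoms)]
    xyz = np.array(coords)

    # overlap sanity check (heavy atoms of distinct residues)
    from scipy.spatial import cKDTree

    heavy = np.array([not a.is_hydrogen for a in atoms])
    tree = cKDTree(xyz[heavy])
    heavy_idx = np.flatnonzero(heavy)
    clashes = [
        (i, j)
        for i, j in tree.query_pairs(r=0.4)
        if atoms[heavy_idx[i]].res_id != atoms[heavy_idx[j]].res_id
        or atoms[heavy_idx[i]].subunit != atoms[heavy_idx[j]].subunit
    ]
    if clashes:
        i, j = clashes[0]
        a, b = atoms[heavy_idx[i]], atoms[heavy_idx[j]]
        raise ValueError(
            "infeasible toy geometry: overlapping atoms "
            f"{a.res_name}{a.res_id}:{a.name}/su{a.subunit} and "
            f"{b.res_name}{b.res_id}:{b.name}/su{b.subunit}"
        )

    topo = Topology(
        atoms,
        domain_labels={"HCN-domain": (1, 5), "TM": (28, pore_res[-1]),
                       "CL": (50, spec.donor_res_id)},
    )
    frame = Frame(replica_id=0, frame_index=0, coords=xyz)
    return Ensemble(topology=topo, frames=[frame], state_label="start")


# ---------------------------------------------------------------------------
# ensemble generators
# ---------------------------------------------------------------------------


def _rot_z(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _amplitude_vector(topo: Topology, spec: EnsembleSpec) -> np.ndarray:
    amp = np.full(len(topo), spec.noise_amplitude)
    for res, a in spec.noise_amplitudes.items():
        amp[topo.res_ids == res] = a
    return amp


def generate_rotated_ensemble(
    start: Ensemble, spec: EnsembleSpec
) -> Ensemble:
    """Ensemble with a rotated CL-CNBD block plus harmonic positional noise.

    Per frame and per subunit, an angle θ ~ N(rotation_mean, rotation_sd)
    is drawn independently and the subunit's CL-block atoms (residues in
    the ``CL`` domain label) are rotated about the pore (z) axis by θ; all
    atoms then receive independent isotropic Gaussian noise with their
    residue's amplitude (pore and HCN-domain atoms receive noise only).
    Ground-truth angles are stored in ``ensemble.truth['rotation_deg']``
    as an (n_replicas, n_frames, 4) array.  Bit-reproducible given
    (spec, seed); replicas use independent spawned RNG streams.
    """
    topo = start.topology
    base = start.frames[0].coords
    lo, hi = topo.domain_labels["CL"]
    cl_mask = [
        np.flatnonzero((topo.res_ids >= lo) & (topo.res_ids <= hi)
                       & (topo.subunits == s))
        for s in range(4)
    ]
    amp = _amplitude_vector(topo, spec)[:, None]

    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_replicas)
    frames: list[Frame] = []
    truth = np.zeros((spec.n_replicas, spec.n_frames, 4))
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        for f in range(spec.n_frames):
            coords = base.copy()
            for s in range(4):
                theta = rng.normal(spec.rotation_mean, spec.rotation_sd)
                truth[r, f, s] = theta
                coords[cl_mask[s]] = coords[cl_mask[s]] @ _rot_z(theta).T
            coords += rng.standard_normal(coords.shape) * amp
            frames.append(Frame(replica_id=r, frame_index=f, coords=coords))
    ens = Ensemble(topology=topo, frames=frames, state_label=start.state_label)
    ens.truth["rotation_deg"] = truth
    return ens


def generate_contact_trajectory(
    start: Ensemble,
    p: float,
    n_frames: int,
    seed: int = 0,
    n_replicas: int = 1,
    off_distance: float = 6.0,
) -> Ensemble:
    """Frames in which each donor/acceptor pair is bonded with probability p.

    For every frame and every directed opposite pair (donor subunit i,
    acceptor site on i+2), a Bernoulli(p) draw decides whether the
    acceptor site residue stays in its starting contact geometry
    (d = contact_distance, angle 170°) or is displaced along the
    donor→acceptor direction to ``off_distance``.  Draws are recorded in
    ``ensemble.truth['bonded']`` with shape (n_replicas, n_frames, 4),
    indexed by donor subunit.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    topo = start.topology
    base = start.frames[0].coords
    site_res = topo.domain_labels["HCN-domain"][1]  # site residue id

    site_idx = [np.flatnonzero((topo.res_ids == site_res) & (topo.subunits == s))
                for s in range(4)]
    o_idx = [
        int(site_idx[s][np.flatnonzero(topo.names[site_idx[s]] == "O")[0]])
        for s in range(4)
    ]
    nz_idx = [
        int(np.flatnonzero((topo.names == "NZ") & (topo.subunits == s))[0])
        for s in range(4)
    ]

    # displacement that moves the site of subunit j from contact to off
    shift = []
    for j in range(4):
        donor = (j + 2) % 4
        v = base[o_idx[j]] - base[nz_idx[donor]]
        d0 = np.linalg.norm(v)
        shift.append(v / d0 * (off_distance - d0))

    streams = np.random.SeedSequence(seed).spawn(n_replicas)
    frames: list[Frame] = []
    truth = np.zeros((n_replicas, n_frames, 4), dtype=bool)
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        for f in range(n_frames):
            coords = base.copy()
            for donor in range(4):
                j = (donor + 2) % 4  # acceptor-site owner
                bonded = rng.random() < p
                truth[r, f, donor] = bonded
                if not bonded:
                    coords[site_idx[j]] += shift[j]
            frames.append(Frame(replica_id=r, frame_index=f, coords=coords))
    ens = Ensemble(topology=topo, frames=frames, state_label=start.state_label)
    ens.truth["bonded"] = truth
    return ens


# ---------------------------------------------------------------------------
# electrophysiology / cPCF generators
# ---------------------------------------------------------------------------


def _tau_of_v(spec: EphysSpec, V: float) -> float:
    # activation slows toward depolarised voltages
    v_min = min(spec.voltages)
    return spec.tau_ref * math.exp((V - v_min) / 40.0)


def generate_activation_traces(
    spec: EphysSpec = EphysSpec(),
) -> tuple[list[ActivationRecording], dict[tuple[str, float], pd.DataFrame]]:
    """Synthetic voltage-family recordings.

    Returns ``n_recordings`` tail-amplitude recordings whose relative
    amplitudes follow the Boltzmann curve with Gaussian noise, plus one
    activation time course per (recording, voltage): a delayed rising
    exponential with τ(V) and optional trace noise.  Deterministic given
    the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    V = np.asarray(spec.voltages, float)
    recordings: list[ActivationRecording] = []
    traces: dict[tuple[str, float], pd.DataFrame] = {}
    for k in range(spec.n_recordings):
        ideal = boltzmann(V, spec.V_half, spec.z_delta, spec.amp_satV)
        amps = ideal + rng.normal(0.0, spec.noise_sd, size=V.shape)
        rec_id = f"rec{k:03d}"
        recordings.append(
            ActivationRecording(command_voltages=V, tail_amplitudes=amps,
                                cAMP_state="zero", recording_id=rec_id)
        )
        for v, a in zip(V, ideal):
            tau = _tau_of_v(spec, float(v))
            t = np.arange(0.0, spec.delay + 5.0 * tau, tau / 50.0)
            rise = np.where(
                t < spec.delay, 0.0,
                a * (1.0 - np.exp(-(t - spec.delay) / tau)),
            )
            if spec.trace_noise_sd > 0:
                rise = rise + rng.normal(0.0, spec.trace_noise_sd * max(a, 1e-12),
                                         size=t.shape)
            traces[(rec_id, float(v))] = pd.DataFrame(
                {"t_ms": t, "I": rise, "tau_true": tau, "delay_true": spec.delay}
            )
    return recordings, traces


def generate_binding_data(spec: EphysSpec = EphysSpec()) -> pd.DataFrame:
    """Averaged concentration–binding table governed by the Hill equation.

    ``n_patches`` noisy response sets are averaged per concentration, the
    way cPCF patches are pooled before fitting.  Columns:
    ``concentration_uM``, ``F_over_Fmax``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    c = np.asarray(spec.concentrations, float)
    ideal = hill(c, spec.BC50, spec.H)
    resp = ideal[None, :] + rng.normal(0.0, spec.noise_sd,
                                       size=(spec.n_patches, c.size))
    return pd.DataFrame({"concentration_uM": c, "F_over_Fmax": resp.mean(axis=0)})


def generate_cpcf_images(
    bound_fraction: float,
    scale: float = 1.4,
    noise_sd: float = 1.0,
    F_max: float = 100.0,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
) -> CPCFMeasurement:
    """Two-channel cPCF image pair with a known dome bound fraction.

    The red reference channel is uniform free-dye signal over
    bath ∪ pipette ∪ dome; green = scale·red plus a dome-only bound
    component ``bound_fraction · F_max`` and Gaussian noise on both
    channels.
    """
    rng = np.random.default_rng(seed)
    rows, cols = np.indices(shape)
    bath = cols < 20
    pipette = (rows >= 28) & (rows <= 36) & (cols >= 46)
    dome = (rows - 32) ** 2 + (cols - 38) ** 2 <= 25
    solution = bath | pipette | dome

    red = np.where(solution, 50.0, 0.0)
    green = scale * red
    green = green + np.where(dome, bound_fraction * F_max, 0.0)
    red = red + rng.normal(0.0, noise_sd, shape)
    green = green + rng.normal(0.0, noise_sd, shape)
    return CPCFMeasurement(green=green, red=red, roi_dome=dome, roi_bath=bath,
                           roi_pipette=pipette, F_max=F_max)
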