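import numpy as np
import pytest

from channelrot import rotation as rot
from channelrot.model_io import AtomRecord, Ensemble, Frame, Topology
from channelrot.synthetic import ToyTetramerSpec, build_toy_tetramer

#: rotation-reference parameters matching the toy tetramer's miniature numbering
TOY_ROT_KWARGS = dict(
    elbow_res=(60, 61, 62, 63),
    pore_res_upper=36,
    pore_res_lower=32,
    pore_span=tuple(range(28, 45)),
)


@pytest.fixture(scope="session")
def toy_start() -> Ensemble:
    return build_toy_tetramer(ToyTetramerSpec())


@pytest.fixture(scope="session")
def toy_reference(toy_start):
    return rot.build_rotation_reference(toy_start, **TOY_ROT_KWARGS)


def make_minimal_tetramer(extra_per_subunit: int = 5) -> tuple[Topology, np.ndarray]:
    """Tiny hand-built tetramer: per subunit one Lys-like donor (NZ + three
    HZ hydrogens), one Met-like acceptor (backbone O) and a few filler CA
    atoms.  Coordinates are a deterministic spread; tests randomise them."""
    atoms = []
    coords = []
    rng = np.random.default_rng(7)
    serial = 0
    for s in range(4):
        base = np.array([12.0 * s, 0.0, 0.0])
        for name, elem, res_name, res_id, is_h, is_bb in [
            ("NZ", "N", "LYS", 9, False, False),
            ("HZ1", "H", "LYS", 9, True, False),
            ("HZ2", "H", "LYS", 9, True, False),
            ("HZ3", "H", "LYS", 9, True, False),
            ("O", "O", "MET", 2, False, True),
        ]:
            serial += 1
            atoms.append(AtomRecord(serial, name, elem, res_name, res_id, s,
                                    is_h, is_bb))
            coords.append(base + rng.uniform(-2, 2, 3))
        for k in range(extra_per_subunit):
            serial += 1
            atoms.append(AtomRecord(serial, "CA", "C", "ALA", 20 + k, s,
                                    False, True))
            coords.append(base + rng.uniform(-2, 2, 3))
    return Topology(atoms), np.array(coords)


@pytest.fixture()
def minimal_tetramer():
    return make_minimal_tetramer()


def random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation plus a translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-20, 20, 3)
    return R, t


def transform_ensemble(ens: Ensemble, per_frame: bool, seed: int = 0) -> Ensemble:
    """Apply random rigid-body transforms to an ensemble's frames."""
    rng = np.random.default_rng(seed)
    R, t = random_rigid_transform(rng)
    frames = []
    for f in ens.frames:
        if per_frame:
            R, t = random_rigid_transform(rng)
        frames.append(Frame(f.replica_id, f.frame_index, f.coords @ R.T + t))
    out = Ensemble(topology=ens.topology, frames=frames,
                   state_label=ens.state_label)
    out.truth = ens.truth
    return out
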