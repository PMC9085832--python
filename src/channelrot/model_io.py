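"""Domain types for tetrameric structural ensembles and multi-model PDB I/O.

The central container is an :class:`Ensemble`: a fixed :class:`Topology`
(atoms of a C4-symmetric homotetramer) plus a list of :class:`Frame` objects,
one per stored conformation.  Frames are grouped by MD replica; one
multi-model PDB file holds one replica, with one ``MODEL``/``ENDMDL`` block
per frame.  All coordinates are in Ångström.

Subunits are indexed 0..3; the diagonal ("opposite") partner of subunit
``i`` is ``(i + 2) % 4`` and the adjacent partner is ``(i + 1) % 4``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "Ensemble",
    "SelectionSpec",
    "SelectionError",
    "FormatError",
    "resolve_selection",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_ensemble_glob",
    "DEFAULT_CHAIN_MAP",
]

#: default mapping from PDB chain ID to subunit index
DEFAULT_CHAIN_MAP: Mapping[str, int] = {"A": 0, "B": 1, "C": 2, "D": 3}

# backbone atom names (protein), hydrogens included
_BACKBONE_NAMES = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3"}
)


class FormatError(ValueError):
    """A structure file violates the multi-model layout this package expects."""


class SelectionError(ValueError):
    """An atom selection resolved to an empty set."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology.

    ``res_id`` follows the numbering used for the system at hand (mHCN2
    numbering 136–650 for the real channel; toy systems use a miniature
    numbering with a documented mapping).
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    subunit: int
    is_hydrogen: bool = False
    is_backbone: bool = False

    def __post_init__(self) -> None:
        if self.subunit not in (0, 1, 2, 3):
            raise ValueError(f"subunit must be 0..3, got {self.subunit}")


def _classify(name: str, element: str) -> tuple[bool, bool]:
    is_h = element.upper() == "H" or (not element and name.startswith("H"))
    return is_h, name in _BACKBONE_NAMES


class Topology:
    """Ordered atom list of a homotetramer plus cached index arrays."""

    subunit_count = 4

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        domain_labels: Mapping[str, tuple[int, int]] | None = None,
    ) -> None:
        self.atoms = list(atoms)
        #: residue-range annotation, label -> inclusive (first, last) res_id
        self.domain_labels = dict(domain_labels or {})
        self.res_ids = np.array([a.res_id for a in self.atoms], dtype=int)
        self.subunits = np.array([a.subunit for a in self.atoms], dtype=int)
        self.names = np.array([a.name for a in self.atoms])
        self.res_names = np.array([a.res_name for a in self.atoms])
        self.is_hydrogen = np.array([a.is_hydrogen for a in self.atoms])
        self.is_backbone = np.array([a.is_backbone for a in self.atoms])

    def __len__(self) -> int:
        return len(self.atoms)

    @staticmethod
    def opposite_map(i: int) -> int:
        return (i + 2) % 4

    @staticmethod
    def adjacent_map(i: int) -> int:
        return (i + 1) % 4

    def residue_res_ids(self, subunit: int | None = None) -> np.ndarray:
        mask = np.ones(len(self), dtype=bool)
        if subunit is not None:
            mask &= self.subunits == subunit
        return np.unique(self.res_ids[mask])

    def domain_res_ids(self, label: str) -> np.ndarray:
        lo, hi = self.domain_labels[label]
        ids = np.unique(self.res_ids)
        return ids[(ids >= lo) & (ids <= hi)]


@dataclass
class Frame:
    """Coordinates (Å) of every topology atom at one stored time point."""

    replica_id: int
    frame_index: int
    coords: np.ndarray  # (n_atoms, 3) float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")


@dataclass
class Ensemble:
    """A topology plus frames from one or more independent replicas."""

    topology: Topology
    frames: list[Frame]
    state_label: str = "apo-WT"
    #: optional per-frame ground truth from a generator (degrees)
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.topology)
        for f in self.frames:
            if f.coords.shape[0] != n:
                raise ValueError(
                    f"frame {f.frame_index} has {f.coords.shape[0]} atoms, "
                    f"topology has {n}"
                )

    @property
    def replica_ids(self) -> list[int]:
        seen: dict[int, None] = {}
        for f in self.frames:
            seen.setdefault(f.replica_id, None)
        return list(seen)

    def by_replica(self) -> dict[int, list[Frame]]:
        out: dict[int, list[Frame]] = {}
        for f in self.frames:
            out.setdefault(f.replica_id, []).append(f)
        return out

    def coords_array(self) -> np.ndarray:
        """All frame coordinates stacked to shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coords for f in self.frames])


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

#: recognised atom_filter values for SelectionSpec
ATOM_FILTERS = (
    "CA",
    "CB",
    "backbone-O",
    "sidechain-nonH",
    "sidechain-O",
    "sidechain-N",
    "all-nonH",
    "custom",
)


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection: residues x subunits x an atom filter.

    ``res_ids=None`` selects all residues; ``subunits=None`` all four.
    ``atom_filter='custom'`` uses the explicit ``names`` list.
    """

    res_ids: tuple[int, ...] | None = None
    subunits: tuple[int, ...] | None = None
    atom_filter: str = "all-nonH"
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.atom_filter not in ATOM_FILTERS:
            raise ValueError(f"unknown atom_filter {self.atom_filter!r}")
        if self.res_ids is not None:
            object.__setattr__(self, "res_ids", tuple(sorted(set(self.res_ids))))
        if self.subunits is not None:
            object.__setattr__(self, "subunits", tuple(sorted(set(self.subunits))))


def resolve_selection(topology: Topology, spec: SelectionSpec) -> np.ndarray:
    """Resolve a :class:`SelectionSpec` to a sorted array of atom indices.

    Raises :class:`SelectionError` if the selection is empty (e.g. a glycine
    with ``sidechain-nonH``).
    """
    mask = np.ones(len(topology), dtype=bool)
    if spec.res_ids is not None:
        mask &= np.isin(topology.res_ids, np.asarray(spec.res_ids))
    if spec.subunits is not None:
        mask &= np.isin(topology.subunits, np.asarray(spec.subunits))

    f = spec.atom_filter
    if f == "CA":
        mask &= topology.names == "CA"
    elif f == "CB":
        mask &= topology.names == "CB"
    elif f == "backbone-O":
        mask &= topology.names == "O"
    elif f == "sidechain-nonH":
        mask &= ~topology.is_backbone & ~topology.is_hydrogen
    elif f == "sidechain-O":
        mask &= ~topology.is_backbone & ~topology.is_hydrogen
        mask &= np.char.startswith(topology.names.astype(str), "O")
    elif f == "sidechain-N":
        mask &= ~topology.is_backbone & ~topology.is_hydrogen
        mask &= np.char.startswith(topology.names.astype(str), "N")
    elif f == "all-nonH":
        mask &= ~topology.is_hydrogen
    elif f == "custom":
        mask &= np.isin(topology.names, np.asarray(spec.names))

    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection resolved to no atoms: {spec}")
    return idx


# ---------------------------------------------------------------------------
# multi-model PDB I/O (via gemmi)
# ---------------------------------------------------------------------------


def read_multimodel_pdb(
    path: str | Path,
    subunit_chain_map: Mapping[str, int] | None = None,
    replica_id: int = 0,
    state_label: str = "apo-WT",
    domain_labels: Mapping[str, tuple[int, int]] | None = None,
) -> Ensemble:
    """Read a multi-model PDB file into an :class:`Ensemble`.

    Each MODEL block becomes one :class:`Frame`; the atom order must be
    identical in every model, otherwise a :class:`FormatError` naming the
    offending model is raised.  Chains are mapped to subunit indices through
    ``subunit_chain_map`` (default A..D -> 0..3).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    chain_map = dict(subunit_chain_map or DEFAULT_CHAIN_MAP)

    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise FormatError(f"{path}: no MODEL records found")

    atoms: list[AtomRecord] = []
    signature: list[tuple[str, int, str, str]] = []
    serial = 0
    for chain in st[0]:
        if chain.name not in chain_map:
            raise FormatError(f"{path}: chain {chain.name!r} not in subunit map")
        sub = chain_map[chain.name]
        for res in chain:
            for atom in res:
                serial += 1
                elem = atom.element.name
                is_h, is_bb = _classify(atom.name, elem)
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=atom.name,
                        element=elem,
                        res_name=res.name,
                        res_id=res.seqid.num,
                        subunit=sub,
                        is_hydrogen=is_h,
                        is_backbone=is_bb,
                    )
                )
                signature.append((chain.name, res.seqid.num, res.name, atom.name))
    topology = Topology(atoms, domain_labels=domain_labels)

    frames: list[Frame] = []
    for m_idx, model in enumerate(st):
        coords = []
        sig = []
        for chain in model:
            for res in chain:
                for atom in res:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    sig.append((chain.name, res.seqid.num, res.name, atom.name))
        if sig != signature:
            raise FormatError(
                f"{path}: model {m_idx + 1} atom list differs from model 1 "
                f"({len(sig)} vs {len(signature)} atoms)"
            )
        frames.append(
            Frame(replica_id=replica_id, frame_index=m_idx, coords=np.array(coords))
        )
    return Ensemble(topology=topology, frames=frames, state_label=state_label)


_CHAIN_FOR_SUBUNIT = "ABCD"


def write_multimodel_pdb(ensemble: Ensemble, path: str | Path) -> list[Path]:
    """Write an ensemble as one multi-model PDB file per replica.

    Chain IDs A–D correspond to subunits 0–3; coordinates keep PDB's three
    decimals.  With a single replica the file is written to ``path`` as
    given; with several, ``_rep<id>`` is appended before the suffix.
    Returns the list of files written.
    """
    if not ensemble.frames:
        raise ValueError("refusing to write an ensemble with no frames")
    path = Path(path)
    by_rep = ensemble.by_replica()
    written: list[Path] = []
    multi = len(by_rep) > 1
    for rep_id, frames in by_rep.items():
        out = (
            path.with_name(f"{path.stem}_rep{rep_id}{path.suffix}") if multi else path
        )
        # group atom indices by (subunit, res_id), preserving order
        groups: dict[int, dict[int, list[int]]] = {}
        for i, rec in enumerate(ensemble.topology.atoms):
            groups.setdefault(rec.subunit, {}).setdefault(rec.res_id, []).append(i)

        st = gemmi.Structure()
        st.name = ensemble.state_label
        for m_idx, frame in enumerate(frames):
            # gemmi add_* methods copy, so residues/chains are built fully
            # before being attached
            model = gemmi.Model(m_idx + 1)
            for sub in sorted(groups):
                chain = gemmi.Chain(_CHAIN_FOR_SUBUNIT[sub])
                for res_id, atom_idx in groups[sub].items():
                    res = gemmi.Residue()
                    res.name = ensemble.topology.atoms[atom_idx[0]].res_name
                    res.seqid = gemmi.SeqId(res_id, " ")
                    for i in atom_idx:
                        rec = ensemble.topology.atoms[i]
                        atom = gemmi.Atom()
                        atom.name = rec.name
                        atom.element = gemmi.Element(rec.element or rec.name[0])
                        atom.pos = gemmi.Position(*frame.coords[i])
                        res.add_atom(atom)
                    chain.add_residue(res)
                model.add_chain(chain)
            st.add_model(model)
        st.setup_entities()
        out.write_text(st.make_pdb_string())
        written.append(out)
    return written


def read_ensemble_glob(
    pattern: str,
    subunit_chain_map: Mapping[str, int] | None = None,
    state_label: str = "apo-WT",
    replica_regex: str = r"_rep(\d+)",
    domain_labels: Mapping[str, tuple[int, int]] | None = None,
) -> Ensemble:
    """Read every replica file matching a glob into one ensemble.

    The replica id is parsed from the filename with ``replica_regex``
    (first capture group); files without a match are numbered in sort order.
    """
    files = sorted(Path().glob(pattern)) if not Path(pattern).is_absolute() else sorted(
        Path(pattern).parent.glob(Path(pattern).name)
    )
    if not files:
        raise FileNotFoundError(f"no files match {pattern!r}")
    frames: list[Frame] = []
    topology: Topology | None = None
    for k, f in enumerate(files):
        m = re.search(replica_regex, f.name)
        rep = int(m.group(1)) if m else k
        ens = read_multimodel_pdb(
            f, subunit_chain_map, replica_id=rep, state_label=state_label,
            domain_labels=domain_labels,
        )
        if topology is None:
            topology = ens.topology
        elif len(ens.topology) != len(topology):
            raise FormatError(f"{f}: atom count differs from first replica")
        frames.extend(ens.frames)
    assert topology is not None
    return Ensemble(topology=topology, frames=frames, state_label=state_label)
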