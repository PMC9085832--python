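"""Per-frame hydrogen-bond / salt-bridge detection and occurrence frequencies.

A contact is scored per frame with the geometric criteria used throughout
the analysis: heavy-atom donor–acceptor distance <= 3.5 Å and a
donor–H–acceptor angle (vertex at the hydrogen) >= 120°.  Salt bridges are
scored with the same criteria on the charged-group atoms (side-chain N
donors against carboxylate O acceptors).  For hydrogen-free models a
distance-only mode waives the angle term and flags the result.

Occurrence frequency is the fraction of frames in which *any*
donor-atom/hydrogen/acceptor-atom combination passes.  All four symmetric
placements of a contact (donor subunit i against acceptor subunit i+1 or
i+2) are scored, so a 20-replica ensemble yields n = 4 x 20 = 80 values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model_io import Ensemble, Frame, SelectionSpec, SelectionError, Topology, resolve_selection
from .ensemble_stats import summarize

__all__ = [
    "ContactDefinition",
    "ContactFrequencyResult",
    "attached_hydrogens",
    "detect_hbond",
    "contact_frequency",
    "min_distance",
    "salt_bridge_frequency",
]

log = logging.getLogger(__name__)

_BASIC = {"LYS", "ARG", "HIS"}
_ACIDIC = {"ASP", "GLU"}

_ROLE_OFFSET = {"opposite": 2, "adjacent": 1, "same": 0}


@dataclass(frozen=True)
class ContactDefinition:
    """Donor/acceptor specification for an inter-subunit contact.

    The donor residue sits on subunit *i*; the acceptor residue sits on
    subunit *i + 2* (``role='opposite'``) or *i + 1* (``'adjacent'``).
    """

    donor_res_id: int
    donor_filter: str  # SelectionSpec atom_filter for donor heavy atoms
    acceptor_res_id: int
    acceptor_filter: str
    role: str = "opposite"
    distance_cutoff: float = 3.5  # Å
    angle_cutoff: float = 120.0  # degrees, donor–H–acceptor, vertex at H
    kind: str = "hbond"

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be > 0")
        if not 0 < self.angle_cutoff <= 180:
            raise ValueError("angle_cutoff must be in (0, 180]")
        if self.role not in _ROLE_OFFSET:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class ContactFrequencyResult:
    """Per-(subunit pair, replica) occupancy fractions plus their summary."""

    definition: ContactDefinition
    per_pair_per_replica: pd.DataFrame  # columns: donor_subunit, acceptor_subunit, replica, frequency
    mean: float
    sem: float
    n: int
    distance_only: bool = False

    def __post_init__(self) -> None:
        f = self.per_pair_per_replica["frequency"].to_numpy()
        assert np.all((f >= 0) & (f <= 1))


def attached_hydrogens(
    topology: Topology, coords: np.ndarray, donor_index: int
) -> list[int]:
    """Hydrogens bonded to a donor heavy atom.

    Resolution is by PDB naming convention first (hydrogen name 'H' +
    the donor's remoteness suffix, e.g. HZ1/HZ2/HZ3 on NZ, HG1 on OG1,
    bare 'H' on backbone N), with a geometric fallback: any hydrogen of
    the same residue within 1.2 Å of the donor.
    """
    rec = topology.atoms[donor_index]
    same_res = np.flatnonzero(
        (topology.res_ids == rec.res_id)
        & (topology.subunits == rec.subunit)
        & topology.is_hydrogen
    )
    if same_res.size == 0:
        return []
    suffix = rec.name[1:]  # e.g. NZ -> 'Z', N -> '', OG1 -> 'G1'
    by_name = [
        int(i)
        for i in same_res
        if _h_matches(topology.atoms[i].name, suffix)
    ]
    if by_name:
        return by_name
    d = np.linalg.norm(coords[same_res] - coords[donor_index], axis=1)
    return [int(i) for i in same_res[d < 1.2]]


def _h_matches(h_name: str, donor_suffix: str) -> bool:
    if not h_name.startswith("H"):
        return False
    rest = h_name[1:]
    if donor_suffix == "":
        return rest == "" or rest in {"1", "2", "3"}
    if rest == donor_suffix:
        return True
    # HZ1/HZ2/HZ3 on NZ; HG11 on CG1 etc.
    return rest.rstrip("0123456789") == donor_suffix.rstrip("0123456789") == donor_suffix


def _dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    """Donor–H–acceptor angle in degrees (vertex at H); NaN if degenerate."""
    v1 = d - h
    v2 = a - h
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        return float("nan")
    c = float(np.dot(v1, v2) / (n1 * n2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


_degenerate_logged = False


def detect_hbond(
    frame: Frame,
    donor_atom: int,
    donor_hydrogens: list[int],
    acceptor_atom: int,
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
    distance_only: bool = False,
) -> bool:
    """True iff the donor/acceptor pair is hydrogen-bonded in this frame.

    Criterion: heavy-atom distance <= ``distance_cutoff`` AND some attached
    hydrogen gives a donor–H–acceptor angle >= ``angle_cutoff``.  If the
    model carries no hydrogens (``distance_only`` or an empty hydrogen
    list with ``distance_only=True`` upstream) only the distance is tested.
    Degenerate geometry (H coincident with donor or acceptor) fails the
    angle criterion.
    """
    global _degenerate_logged
    c = frame.coords
    dist = float(np.linalg.norm(c[donor_atom] - c[acceptor_atom]))
    if dist > distance_cutoff:
        return False
    if distance_only:
        return True
    for h in donor_hydrogens:
        ang = _dha_angle(c[donor_atom], c[h], c[acceptor_atom])
        if math.isnan(ang):
            if not _degenerate_logged:
                log.warning("degenerate D/H geometry; angle criterion fails")
                _degenerate_logged = True
            continue
        if ang >= angle_cutoff:
            return True
    return False


def contact_frequency(
    ensemble: Ensemble, definition: ContactDefinition
) -> ContactFrequencyResult:
    """Occurrence frequency of a contact across an ensemble.

    For every (donor subunit i, acceptor subunit role(i)) pair and every
    replica, the fraction of frames in which at least one donor-atom /
    acceptor-atom combination satisfies :func:`detect_hbond`; summarised
    as mean ± SEM over all pair × replica values.
    """
    topo = ensemble.topology
    offset = _ROLE_OFFSET[definition.role]
    if offset == 0:
        raise ValueError("contact role must relate two distinct subunits")

    pairs = [(i, (i + offset) % 4) for i in range(4)]
    # resolve atoms once per pair
    pair_atoms = []
    any_h = False
    for di, ai in pairs:
        d_idx = resolve_selection(
            topo,
            SelectionSpec(res_ids=(definition.donor_res_id,), subunits=(di,),
                          atom_filter=definition.donor_filter),
        )
        a_idx = resolve_selection(
            topo,
            SelectionSpec(res_ids=(definition.acceptor_res_id,), subunits=(ai,),
                          atom_filter=definition.acceptor_filter),
        )
        h_map = {
            int(d): attached_hydrogens(topo, ensemble.frames[0].coords, int(d))
            for d in d_idx
        }
        any_h = any_h or any(h_map.values())
        pair_atoms.append((di, ai, d_idx, a_idx, h_map))

    distance_only = not any_h
    if distance_only:
        log.info("no donor hydrogens found: falling back to distance-only mode")

    rows = []
    for rep, frames in ensemble.by_replica().items():
        for di, ai, d_idx, a_idx, h_map in pair_atoms:
            hits = 0
            for frame in frames:
                found = False
                for d in d_idx:
                    for a in a_idx:
                        if detect_hbond(
                            frame,
                            int(d),
                            h_map[int(d)],
                            int(a),
                            definition.distance_cutoff,
                            definition.angle_cutoff,
                            distance_only=distance_only,
                        ):
                            found = True
                            break
                    if found:
                        break
                hits += found
            rows.append(
                {
                    "donor_subunit": di,
                    "acceptor_subunit": ai,
                    "replica": rep,
                    "frequency": hits / len(frames),
                }
            )
    df = pd.DataFrame(rows)
    mean, sem, n = summarize(df["frequency"].to_numpy())
    return ContactFrequencyResult(
        definition=definition,
        per_pair_per_replica=df,
        mean=mean,
        sem=sem,
        n=n,
        distance_only=distance_only,
    )


def min_distance(frame: Frame, selection_a: np.ndarray, selection_b: np.ndarray) -> float:
    """Minimum pairwise Euclidean distance (Å) between two atom selections."""
    a = np.atleast_1d(np.asarray(selection_a))
    b = np.atleast_1d(np.asarray(selection_b))
    if a.size == 0 or b.size == 0:
        raise SelectionError("min_distance requires non-empty selections")
    return float(cdist(frame.coords[a], frame.coords[b]).min())


def salt_bridge_frequency(
    ensemble: Ensemble,
    basic_res_id: int,
    acidic_res_id: int,
    role: str = "opposite",
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
) -> ContactFrequencyResult:
    """Salt-bridge occurrence frequency between a basic and an acidic residue.

    Reuses the hydrogen-bond criteria on the charged groups: side-chain N
    donors of Lys/Arg/His against side-chain O acceptors of Asp/Glu.
    """
    topo = ensemble.topology
    for res_id, allowed, label in (
        (basic_res_id, _BASIC, "basic"),
        (acidic_res_id, _ACIDIC, "acidic"),
    ):
        names = set(topo.res_names[topo.res_ids == res_id])
        if not names:
            raise SelectionError(f"residue {res_id} not found")
        if not names & allowed:
            raise ValueError(
                f"residue {res_id} ({'/'.join(sorted(names))}) is not {label}"
            )
    definition = ContactDefinition(
        donor_res_id=basic_res_id,
        donor_filter="sidechain-N",
        acceptor_res_id=acidic_res_id,
        acceptor_filter="sidechain-O",
        role=role,
        distance_cutoff=distance_cutoff,
        angle_cutoff=angle_cutoff,
        kind="saltbridge",
    )
    return contact_frequency(ensemble, definition)
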