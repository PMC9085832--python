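"""CL-CNBD rotation about the pore axis, measured as a four-point dihedral.

The rotation of the intracellular C-linker/CNBD block of each subunit is
quantified against a static reference built from the starting structure:

* point I   — per subunit, centroid of the Cα atoms of the C-linker elbow
  terminal residues (A′-helix tip), taken from the starting structure;
* point II  — centroid of the Cα atoms of the upper pore residue over all
  four subunits (on the pore axis by symmetry);
* point III — the same for the lower pore residue;
* point IV  — the elbow centroid of the current frame (dynamic).

After least-squares superposition of the pore onto the starting structure,
the signed dihedral I–II–III–IV measures how far the elbow has swung
azimuthally around the pore axis.  Angles are in degrees in (−180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble_stats import summarize
from .model_io import Ensemble, Frame, SelectionSpec, Topology, resolve_selection

__all__ = [
    "GeometryError",
    "RotationReference",
    "RotationSeries",
    "kabsch",
    "superimpose_pore",
    "dihedral",
    "build_rotation_reference",
    "rotation_angle",
    "rotation_summary",
    "average_structure",
    "DEFAULT_ELBOW_RES",
    "DEFAULT_PORE_UPPER",
    "DEFAULT_PORE_LOWER",
    "DEFAULT_PORE_SPAN",
]

# mHCN2 defaults: elbow M460–H463, pore markers T436 (upper) / I432 (lower),
# S6 gate-region Cα span used for superposition
DEFAULT_ELBOW_RES = (460, 461, 462, 463)
DEFAULT_PORE_UPPER = 436
DEFAULT_PORE_LOWER = 432
DEFAULT_PORE_SPAN = tuple(range(428, 445))


class GeometryError(ValueError):
    """Degenerate geometry: collinear fit selection or point on the axis."""


@dataclass(frozen=True)
class RotationReference:
    """Static reference points and selections for the rotation dihedral."""

    points_I: np.ndarray          # (4, 3), one per subunit
    point_II: np.ndarray          # (3,)
    point_III: np.ndarray         # (3,)
    elbow_selections: tuple       # per-subunit atom index arrays (point IV)
    pore_selection: np.ndarray    # atom indices for superposition
    reference_coords: np.ndarray  # starting-structure coordinates (n_atoms, 3)
    sign_convention: float = 1.0  # multiplier applied to the raw dihedral

    def __post_init__(self) -> None:
        if np.linalg.norm(self.point_II - self.point_III) < 1e-9:
            raise GeometryError("points II and III coincide; axis undefined")


@dataclass
class RotationSeries:
    """Per-frame angles, per-(subunit, replica) means, and the grand summary."""

    per_frame: pd.DataFrame       # columns: subunit, replica, frame, angle_deg
    per_subunit_replica: pd.DataFrame  # columns: subunit, replica, angle_deg
    mean: float
    sem: float
    n: int


# ---------------------------------------------------------------------------
# rigid-body superposition (Kabsch, SVD formulation)
# ---------------------------------------------------------------------------


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t mapping mobile onto target.

    Least-squares rigid-body fit without scaling; reflections are excluded
    by sign-correcting the smallest singular vector.  Returns (R, t) such
    that ``mobile @ R.T + t`` minimises the RMSD to ``target``.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


def _collinear(points: np.ndarray, tol: float = 1e-8) -> bool:
    if len(points) < 3:
        return True
    centred = points - points.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    return bool(s[1] <= tol * max(s[0], 1.0))


def superimpose_pore(
    frame: Frame, reference_frame: Frame, pore_selection: np.ndarray
) -> tuple[Frame, float]:
    """Rigid-body fit of a frame's pore atoms onto a reference frame.

    The whole frame is transformed; the returned RMSD is over the pore
    atoms after the fit.  Raises :class:`GeometryError` for fewer than
    three or collinear fit atoms.
    """
    sel = np.asarray(pore_selection)
    if sel.size < 3:
        raise GeometryError("superposition needs >= 3 atoms")
    ref = reference_frame.coords[sel]
    mob = frame.coords[sel]
    if _collinear(ref) or _collinear(mob):
        raise GeometryError("pore selection is collinear; fit is degenerate")
    R, t = kabsch(mob, ref)
    new_coords = frame.coords @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((new_coords[sel] - ref) ** 2, axis=1))))
    out = Frame(replica_id=frame.replica_id, frame_index=frame.frame_index,
                coords=new_coords)
    return out, rmsd


# ---------------------------------------------------------------------------
# dihedral
# ---------------------------------------------------------------------------


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed four-point dihedral in degrees, atan2 formulation.

    Numerically stable near 0° and 180°; result in (−180, 180].
    """
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n2 = np.linalg.norm(b2)
    if n2 < 1e-12:
        raise GeometryError("central dihedral axis has zero length")
    c1 = np.cross(b1, b2)
    c2 = np.cross(b2, b3)
    if np.linalg.norm(c1) < 1e-12 or np.linalg.norm(c2) < 1e-12:
        raise GeometryError("dihedral undefined: point on the central axis")
    x = float(np.dot(c1, c2))
    y = float(np.dot(np.cross(c1, c2), b2 / n2))
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


# ---------------------------------------------------------------------------
# reference construction and per-frame angle
# ---------------------------------------------------------------------------


def build_rotation_reference(
    starting: Ensemble | Frame,
    topology: Topology | None = None,
    elbow_res: tuple[int, ...] = DEFAULT_ELBOW_RES,
    pore_res_upper: int = DEFAULT_PORE_UPPER,
    pore_res_lower: int = DEFAULT_PORE_LOWER,
    pore_span: tuple[int, ...] = DEFAULT_PORE_SPAN,
    sign_convention: float = 1.0,
) -> RotationReference:
    """Build the static rotation reference from a starting structure.

    Point I is the per-subunit centroid of the elbow Cα atoms; points II
    and III are single centroids of the upper/lower pore-residue Cα atoms
    over all four subunits (unweighted centroids throughout).
    """
    if isinstance(starting, Ensemble):
        topo = starting.topology
        coords = starting.frames[0].coords
    else:
        if topology is None:
            raise ValueError("topology required when passing a bare Frame")
        topo = topology
        coords = starting.coords

    elbow_sels = []
    points_I = []
    for sub in range(4):
        sel = resolve_selection(
            topo, SelectionSpec(res_ids=elbow_res, subunits=(sub,), atom_filter="CA")
        )
        elbow_sels.append(sel)
        points_I.append(coords[sel].mean(axis=0))

    def _axis_point(res_id: int) -> np.ndarray:
        sel = resolve_selection(
            topo, SelectionSpec(res_ids=(res_id,), atom_filter="CA")
        )
        return coords[sel].mean(axis=0)

    pore_sel = resolve_selection(
        topo, SelectionSpec(res_ids=pore_span, atom_filter="CA")
    )
    return RotationReference(
        points_I=np.array(points_I),
        point_II=_axis_point(pore_res_upper),
        point_III=_axis_point(pore_res_lower),
        elbow_selections=tuple(elbow_sels),
        pore_selection=pore_sel,
        reference_coords=coords.copy(),
        sign_convention=sign_convention,
    )


def rotation_angle(frame: Frame, reference: RotationReference, subunit: int) -> float:
    """Signed rotation angle (degrees) of one subunit's elbow for a frame.

    The frame must already be pore-superimposed onto the starting
    structure.  Computed as the dihedral I–II–III–IV with IV the current
    elbow centroid; the sign convention multiplier orients positive with
    the rotation direction seen going from the starting structure to the
    apo wild-type simulations.
    """
    point_IV = frame.coords[reference.elbow_selections[subunit]].mean(axis=0)
    raw = dihedral(
        reference.points_I[subunit], reference.point_II, reference.point_III, point_IV
    )
    return reference.sign_convention * raw


def rotation_summary(ensemble: Ensemble, reference: RotationReference) -> RotationSeries:
    """Per-frame rotation angles aggregated the study's way.

    Every frame is pore-superimposed onto the starting structure, angles
    are measured per subunit, averaged over frames within each
    (subunit, replica), and summarised as grand mean ± SEM over those
    n = subunits × replicas values.
    """
    ref_frame = Frame(replica_id=-1, frame_index=-1,
                      coords=reference.reference_coords)
    rows = []
    for rep, frames in ensemble.by_replica().items():
        for frame in frames:
            fitted, _ = superimpose_pore(frame, ref_frame, reference.pore_selection)
            for sub in range(4):
                rows.append(
                    {
                        "subunit": sub,
                        "replica": rep,
                        "frame": frame.frame_index,
                        "angle_deg": rotation_angle(fitted, reference, sub),
                    }
                )
    per_frame = pd.DataFrame(rows)
    per_sr = (
        per_frame.groupby(["subunit", "replica"], as_index=False)["angle_deg"].mean()
    )
    mean, sem, n = summarize(per_sr["angle_deg"].to_numpy())
    return RotationSeries(per_frame=per_frame, per_subunit_replica=per_sr,
                          mean=mean, sem=sem, n=n)


def average_structure(
    ensemble: Ensemble,
    pore_selection: np.ndarray | None = None,
    align: bool = True,
) -> Frame:
    """Coordinate-wise mean structure over the full ensemble.

    Every frame is first superimposed on the first frame over
    ``pore_selection`` (all non-hydrogen atoms if omitted); pass
    ``align=False`` for frames that are already in a common frame of
    reference.
    """
    if not ensemble.frames:
        raise ValueError("ensemble has no frames")
    first = ensemble.frames[0]
    if len(ensemble.frames) == 1:
        return Frame(replica_id=-1, frame_index=-1, coords=first.coords.copy())
    if pore_selection is None:
        pore_selection = np.flatnonzero(~ensemble.topology.is_hydrogen)
    acc = np.zeros_like(first.coords)
    for frame in ensemble.frames:
        if align:
            fitted, _ = superimpose_pore(frame, first, pore_selection)
            acc += fitted.coords
        else:
            acc += frame.coords
    return Frame(replica_id=-1, frame_index=-1, coords=acc / len(ensemble.frames))
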