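"""Residue-wise side-chain RMSF, significance-masked ΔRMSF, and gate metrics.

RMSF (root mean square fluctuation) measures atomic mobility: per atom,
the RMS displacement from its time-mean position over a replica's frames;
per residue, the unweighted mean over the residue's selected atoms
(all non-hydrogen side-chain atoms by default).  Frames are aligned per
replica onto the replica-average structure over a caller-supplied
alignment selection (pore Cα atoms for the channel analyses); pass
``alignment_selection=None`` for pre-aligned frames.

ΔRMSF between two states is the difference of the per-residue means
(reference minus other), reset to zero wherever a two-sample t-test over
the subunit × replica values does not reach significance — leaving only
the significant mobility changes.

Gate metrics follow the channel geometry: for each gate residue the
Cβ–Cβ distance between the two opposite subunit pairs, (0,2) and (1,3),
per frame, plus the side-chain RMSF of the gate residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble_stats import summarize, two_sample_ttest
from .model_io import Ensemble, Frame, SelectionSpec, SelectionError, resolve_selection
from .rotation import superimpose_pore

__all__ = [
    "RMSFTable",
    "DeltaRMSFTable",
    "GateMetrics",
    "rmsf",
    "delta_rmsf",
    "gate_distances",
    "gate_rmsf",
    "DEFAULT_GATE_RES",
]

log = logging.getLogger(__name__)

#: mHCN2 gate-forming residues I432, T436, Q440
DEFAULT_GATE_RES = (432, 436, 440)


@dataclass
class RMSFTable:
    """Per-(residue, subunit, replica) RMSF values in Å."""

    table: pd.DataFrame  # columns: res_id, subunit, replica, rmsf
    atom_filter: str
    residue_mode: str  # 'atom-mean' or 'pooled'

    def per_residue_samples(self, res_id: int) -> np.ndarray:
        sub = self.table[self.table["res_id"] == res_id]
        return sub["rmsf"].to_numpy()

    def res_ids(self) -> np.ndarray:
        return np.unique(self.table["res_id"].to_numpy())


@dataclass
class DeltaRMSFTable:
    """Significance-masked per-residue RMSF difference (reference − other)."""

    table: pd.DataFrame  # columns: res_id, delta, p_value, masked
    alpha: float


def _replica_rmsf(
    frames: list[Frame],
    sel: np.ndarray,
    align_sel: np.ndarray | None,
) -> np.ndarray:
    """Per-atom RMSF (over ``sel``) for one replica's frames."""
    coords = np.stack([f.coords for f in frames])
    if align_sel is not None:
        # one-pass alignment: fit to first frame, average, refit to average
        first = frames[0]
        fitted = [superimpose_pore(f, first, align_sel)[0].coords for f in frames]
        mean = np.mean(fitted, axis=0)
        mean_frame = Frame(replica_id=-1, frame_index=-1, coords=mean)
        coords = np.stack(
            [superimpose_pore(f, mean_frame, align_sel)[0].coords for f in frames]
        )
    sub = coords[:, sel, :]
    mean_pos = sub.mean(axis=0)
    sq = np.sum((sub - mean_pos) ** 2, axis=2)  # (n_frames, n_sel)
    return np.sqrt(sq.mean(axis=0))


def rmsf(
    ensemble: Ensemble,
    selection: SelectionSpec | None = None,
    alignment_selection: np.ndarray | None = None,
    residue_mode: str = "atom-mean",
) -> RMSFTable:
    """Residue-wise RMSF per (subunit, replica).

    ``selection`` defaults to all non-hydrogen side-chain atoms.  Residues
    with no selected atoms (glycine for side chains) are omitted and
    logged.  ``residue_mode='atom-mean'`` averages the atoms' RMSF values;
    ``'pooled'`` takes the RMS over all the residue's atom displacements.
    """
    topo = ensemble.topology
    if selection is None:
        selection = SelectionSpec(atom_filter="sidechain-nonH")
    if residue_mode not in ("atom-mean", "pooled"):
        raise ValueError(f"unknown residue_mode {residue_mode!r}")
    try:
        sel = resolve_selection(topo, selection)
    except SelectionError:
        raise
    res_of_sel = topo.res_ids[sel]
    sub_of_sel = topo.subunits[sel]

    skipped = set()
    if selection.res_ids is not None:
        wanted = set(selection.res_ids)
        present = set(np.unique(res_of_sel).tolist())
        skipped = wanted - present
        if skipped:
            log.info("residues with no selected atoms omitted: %s", sorted(skipped))

    rows = []
    for rep, frames in ensemble.by_replica().items():
        if len(frames) < 2:
            raise ValueError(f"replica {rep}: RMSF needs >= 2 frames")
        atom_rmsf = _replica_rmsf(frames, sel, alignment_selection)
        for sub in range(4):
            m_sub = sub_of_sel == sub
            for res in np.unique(res_of_sel[m_sub]):
                m = m_sub & (res_of_sel == res)
                if residue_mode == "atom-mean":
                    val = float(atom_rmsf[m].mean())
                else:
                    val = float(np.sqrt(np.mean(atom_rmsf[m] ** 2)))
                rows.append(
                    {"res_id": int(res), "subunit": sub, "replica": rep, "rmsf": val}
                )
    return RMSFTable(
        table=pd.DataFrame(rows),
        atom_filter=selection.atom_filter,
        residue_mode=residue_mode,
    )


def delta_rmsf(
    table_ref: RMSFTable,
    table_other: RMSFTable,
    alpha: float = 0.05,
    variant: str = "welch",
) -> DeltaRMSFTable:
    """Significance-masked ΔRMSF = mean(reference) − mean(other) per residue.

    A residue's delta is reset to zero unless a two-tailed two-sample
    t-test over its subunit × replica samples gives p < ``alpha``
    (no multiple-testing correction: per-residue raw p masking).
    Negative unmasked values mean the residue is more mobile in the
    *other* state.
    """
    ref_ids = set(table_ref.res_ids().tolist())
    other_ids = set(table_other.res_ids().tolist())
    common = sorted(ref_ids & other_ids)
    if ref_ids != other_ids:
        log.info("ΔRMSF restricted to %d residues common to both tables", len(common))
    rows = []
    for res in common:
        a = table_ref.per_residue_samples(res)
        b = table_other.per_residue_samples(res)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"residue {res}: need n >= 2 per group")
        test = two_sample_ttest(a, b, variant=variant, alpha=alpha)
        masked = not test.significant
        delta = 0.0 if masked else float(a.mean() - b.mean())
        rows.append(
            {"res_id": res, "delta": delta, "p_value": test.p_value, "masked": masked}
        )
    return DeltaRMSFTable(table=pd.DataFrame(rows), alpha=alpha)


@dataclass
class GateMetrics:
    """Opposite-pair Cβ–Cβ distances and side-chain RMSF of gate residues."""

    distances: pd.DataFrame       # res_id, pair, replica, frame, distance
    distance_summary: pd.DataFrame  # res_id, mean, sem, n (n = 2 pairs x replicas)
    rmsf_table: RMSFTable | None = None


def gate_distances(
    ensemble: Ensemble, gate_res_ids: tuple[int, ...] = DEFAULT_GATE_RES
) -> GateMetrics:
    """Cβ–Cβ distances between opposite subunits for each gate residue.

    Two opposite pairs, (0,2) and (1,3), per residue per frame; per-replica
    means are aggregated to mean ± SEM over the 2 × replicas values.
    """
    topo = ensemble.topology
    cb_idx = {}
    for res in gate_res_ids:
        for sub in range(4):
            sel = resolve_selection(
                topo, SelectionSpec(res_ids=(res,), subunits=(sub,), atom_filter="CB")
            )
            if sel.size != 1:
                raise SelectionError(f"residue {res} subunit {sub}: expected one Cβ")
            cb_idx[(res, sub)] = int(sel[0])

    rows = []
    for rep, frames in ensemble.by_replica().items():
        for frame in frames:
            for res in gate_res_ids:
                for pair in ((0, 2), (1, 3)):
                    d = float(
                        np.linalg.norm(
                            frame.coords[cb_idx[(res, pair[0])]]
                            - frame.coords[cb_idx[(res, pair[1])]]
                        )
                    )
                    rows.append(
                        {
                            "res_id": res,
                            "pair": f"{pair[0]}-{pair[1]}",
                            "replica": rep,
                            "frame": frame.frame_index,
                            "distance": d,
                        }
                    )
    df = pd.DataFrame(rows)
    per_rep = df.groupby(["res_id", "pair", "replica"], as_index=False)[
        "distance"
    ].mean()
    summary_rows = []
    for res in gate_res_ids:
        vals = per_rep[per_rep["res_id"] == res]["distance"].to_numpy()
        mean, sem, n = summarize(vals)
        summary_rows.append({"res_id": res, "mean": mean, "sem": sem, "n": n})
    return GateMetrics(distances=df, distance_summary=pd.DataFrame(summary_rows))


def gate_rmsf(
    ensemble: Ensemble,
    gate_res_ids: tuple[int, ...] = DEFAULT_GATE_RES,
    alignment_selection: np.ndarray | None = None,
) -> RMSFTable:
    """Side-chain RMSF restricted to the gate-forming residues."""
    return rmsf(
        ensemble,
        SelectionSpec(res_ids=gate_res_ids, atom_filter="sidechain-nonH"),
        alignment_selection=alignment_selection,
    )
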