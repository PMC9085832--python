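"""Orchestration: run the full multi-state structural comparison.

``run_compare`` takes a :class:`RunConfig` describing two or more channel
states (each a glob of multi-model PDB replica files plus a starting
structure), computes contact frequencies, rotation summaries, residue
RMSF and gate metrics per state, then pairwise significance-masked ΔRMSF
tables and t-tests between states, and writes everything as tidy TSVs
plus a human-readable summary.  Outputs are deterministic given inputs;
every file carries the config hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fluctuations as fluc
from . import interactions as inter
from . import rotation as rot
from .ensemble_stats import two_sample_ttest
from .model_io import Ensemble, read_ensemble_glob, read_multimodel_pdb

__all__ = ["RunConfig", "ConfigError", "DataError", "run_compare"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run configuration is malformed."""


class DataError(ValueError):
    """An input file is missing or unreadable."""


@dataclass
class RunConfig:
    """Configuration of a comparison run.

    ``states`` maps a state label (e.g. ``apo-WT``) to a glob of replica
    PDB files; ``starting_structures`` maps the same labels to the
    starting-structure PDB used as rotation reference.  Contact
    definitions are given as dicts with the :class:`ContactDefinition`
    field names.
    """

    states: dict[str, str]
    starting_structures: dict[str, str]
    contacts: list[dict] = field(default_factory=list)
    elbow_res: tuple[int, ...] = rot.DEFAULT_ELBOW_RES
    pore_res_upper: int = rot.DEFAULT_PORE_UPPER
    pore_res_lower: int = rot.DEFAULT_PORE_LOWER
    pore_span: tuple[int, ...] = rot.DEFAULT_PORE_SPAN
    gate_res_ids: tuple[int, ...] = fluc.DEFAULT_GATE_RES
    alpha: float = 0.05
    out_dir: str = "channelrot_out"
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            raw = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        try:
            cfg = cls(
                states=dict(raw["states"]),
                starting_structures=dict(raw["starting_structures"]),
                contacts=list(raw.get("contacts", [])),
                elbow_res=tuple(raw.get("elbow_res", rot.DEFAULT_ELBOW_RES)),
                pore_res_upper=int(raw.get("pore_res_upper", rot.DEFAULT_PORE_UPPER)),
                pore_res_lower=int(raw.get("pore_res_lower", rot.DEFAULT_PORE_LOWER)),
                pore_span=tuple(raw.get("pore_span", rot.DEFAULT_PORE_SPAN)),
                gate_res_ids=tuple(raw.get("gate_res_ids", fluc.DEFAULT_GATE_RES)),
                alpha=float(raw.get("alpha", 0.05)),
                out_dir=str(raw.get("out_dir", "channelrot_out")),
                seed=int(raw.get("seed", 0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"malformed config {path}: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.states:
            raise ConfigError("config needs at least one state")
        missing = set(self.states) - set(self.starting_structures)
        if missing:
            raise ConfigError(f"no starting structure for states: {sorted(missing)}")

    def hash(self) -> str:
        blob = json.dumps(
            {k: sorted(v.items()) if isinstance(v, dict) else v
             for k, v in self.__dict__.items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# channelrot config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _load_state(cfg: RunConfig, label: str) -> tuple[Ensemble, Ensemble]:
    glob_pattern = cfg.states[label]
    try:
        ens = read_ensemble_glob(glob_pattern, state_label=label)
    except FileNotFoundError as exc:
        raise DataError(f"state {label!r}: {exc}") from exc
    try:
        start = read_multimodel_pdb(cfg.starting_structures[label],
                                    state_label=label)
    except FileNotFoundError as exc:
        raise DataError(f"starting structure for {label!r}: {exc}") from exc
    return ens, start


def run_compare(config: RunConfig) -> dict:
    """Run the full comparison; returns a dict of result objects.

    Per state: contact TSVs, rotation TSV, RMSF TSV, gate TSV.  Pairwise
    between states: ΔRMSF tables and t-test tables for rotation and gate
    distances.  A ``summary.txt`` collects mean ± SEM, n and p values.
    """
    config.validate()
    cfg_hash = config.hash()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run_compare: %d states, config %s", len(config.states), cfg_hash)

    results: dict = {"config_hash": cfg_hash, "states": {}, "pairwise": {}}
    summary_lines = [f"channelrot comparison (config {cfg_hash})", ""]

    for label in config.states:
        stage = f"load[{label}]"
        try:
            ens, start = _load_state(config, label)
            stage = f"rotation[{label}]"
            ref = rot.build_rotation_reference(
                start, elbow_res=config.elbow_res,
                pore_res_upper=config.pore_res_upper,
                pore_res_lower=config.pore_res_lower,
                pore_span=config.pore_span,
            )
            rs = rot.rotation_summary(ens, ref)
            stage = f"rmsf[{label}]"
            pore_sel = ref.pore_selection
            rmsf_tab = fluc.rmsf(ens, alignment_selection=pore_sel)
            stage = f"gate[{label}]"
            gate = fluc.gate_distances(ens, config.gate_res_ids)
            gate_rmsf_tab = fluc.gate_rmsf(ens, config.gate_res_ids,
                                           alignment_selection=pore_sel)
            stage = f"contacts[{label}]"
            contact_results = []
            for cdef_raw in config.contacts:
                cdef = inter.ContactDefinition(**cdef_raw)
                contact_results.append(inter.contact_frequency(ens, cdef))
        except Exception as exc:
            raise type(exc)(f"stage {stage} failed: {exc}") from exc

        results["states"][label] = {
            "rotation": rs, "rmsf": rmsf_tab, "gate": gate,
            "gate_rmsf": gate_rmsf_tab, "contacts": contact_results,
        }
        _write_tsv(rs.per_subunit_replica, out / f"rotation_{label}.tsv", cfg_hash)
        _write_tsv(rmsf_tab.table, out / f"rmsf_{label}.tsv", cfg_hash)
        _write_tsv(gate.distance_summary, out / f"gate_{label}.tsv", cfg_hash)
        for k, cres in enumerate(contact_results):
            _write_tsv(cres.per_pair_per_replica,
                       out / f"contact{k}_{label}.tsv", cfg_hash)
        summary_lines.append(
            f"[{label}] rotation {rs.mean:+.2f} ± {rs.sem:.2f} deg (n={rs.n})"
        )
        for cres in contact_results:
            d = cres.definition
            summary_lines.append(
                f"[{label}] contact {d.donor_res_id}->{d.acceptor_res_id} "
                f"({d.role}): {100 * cres.mean:.1f}% ± {100 * cres.sem:.1f}% "
                f"(n={cres.n})"
            )
        for _, row in gate.distance_summary.iterrows():
            summary_lines.append(
                f"[{label}] gate {int(row['res_id'])} Cβ–Cβ "
                f"{row['mean']:.2f} ± {row['sem']:.2f} Å (n={int(row['n'])})"
            )

    labels = list(config.states)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            ra = results["states"][a]
            rb = results["states"][b]
            rot_test = two_sample_ttest(
                ra["rotation"].per_subunit_replica["angle_deg"],
                rb["rotation"].per_subunit_replica["angle_deg"],
                alpha=config.alpha,
            )
            delta = fluc.delta_rmsf(ra["rmsf"], rb["rmsf"], alpha=config.alpha)
            _write_tsv(delta.table, out / f"delta_rmsf_{a}_vs_{b}.tsv", cfg_hash)
            results["pairwise"][(a, b)] = {"rotation_test": rot_test,
                                           "delta_rmsf": delta}
            star = "significant" if rot_test.significant else "n.s."
            summary_lines.append(
                f"[{a} vs {b}] rotation t-test p={rot_test.p_value:.3g} ({star}); "
                f"ΔRMSF: {int((~delta.table['masked']).sum())} of "
                f"{len(delta.table)} residues significant at α={config.alpha}"
            )

    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    results["summary"] = "\n".join(summary_lines)
    return results
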