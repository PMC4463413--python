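"""The virtual-screening funnel: Lipinski pre-filter, Arg168 distance
filtration, bidentate salt-bridge requirement, and loop-interaction selection.

Docked poses are consumed, never generated.  The funnel mirrors the staged
triage used to pick substrate-like LDH-A inhibitor candidates:

1. Library pre-filter — Lipinski's rule of five (MW ≤ 500, logP ≤ 5,
   H-bond donors ≤ 5, H-bond acceptors ≤ 10; all inclusive).
2. Pose intake — a ligand with no docked pose stops here.
3. Arg168 distance filtration — poses are discarded when the carboxyl carbon
   of the ligand sits more than 4.5 Å from the guanidinium carbon (CZ) of
   Arg168; 4.5 Å itself passes.
4. Bidentate requirement — the pose must form twin hydrogen bonds between the
   Arg168 guanidinium and the ligand carboxylate.
5. Loop-interaction selection — at least one (Model 1, NADH present) or two
   (Model 2, apo receptor) distinct satisfied criteria on the mobile loop
   96–111.

A ligand passes a geometric stage if ANY of its poses passes that stage and
every prior geometric stage; the best pose (lowest Arg168 distance, then
highest loop-interaction count, then input order) is the one reported.  The
final expert visual inspection of surviving complexes is deliberately not
automated: the report ends at the loop-criterion stage.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .interactions import (
    CriteriaTable,
    Fingerprint,
    GeometricCutoffs,
    atoms_with_role,
    fingerprint_pose,
)
from .structure_io import Atom, LigandRecord, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorBlock",
    "ScreenConfig",
    "FunnelReport",
    "LigandOutcome",
    "STAGES",
    "lipinski_pass",
    "compute_descriptors",
    "arg168_distance_filter",
    "run_funnel",
    "write_report",
]

STAGES = ("lipinski", "pose_present", "arg168_filter", "bidentate", "loop_criterion")

LIPINSKI_LIMITS = {
    "molecular_weight": 500.0,
    "logp": 5.0,
    "hbond_donors": 5,
    "hbond_acceptors": 10,
}


@dataclass(frozen=True)
class DescriptorBlock:
    """The four rule-of-five descriptors of one library compound."""

    molecular_weight: float  # Da
    logp: float
    hbond_donors: int
    hbond_acceptors: int

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")
        if self.hbond_donors < 0 or self.hbond_acceptors < 0:
            raise ValueError("H-bond counts must be non-negative")


def lipinski_pass(d: DescriptorBlock) -> tuple[bool, list[str]]:
    """Rule-of-five check; every bound is inclusive (MW 500 passes).

    Returns the flag and the list of violated rules by descriptor name.
    """
    violations = [
        name for name, limit in LIPINSKI_LIMITS.items() if getattr(d, name) > limit
    ]
    return (not violations, violations)


def compute_descriptors(record: LigandRecord) -> DescriptorBlock:
    """Compute the rule-of-five descriptors from connectivity.

    MW from standard atomic masses; H-bond donors are N/O atoms carrying at
    least one hydrogen; acceptors are the nitrogen-plus-oxygen count (the
    classic rule-of-five definition); logP from the Crippen atom-contribution
    method.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Lipinski

    mol = record.mol
    if mol is None:
        if not record.smiles:
            raise ValueError(f"ligand {record.id!r}: no connectivity available")
        mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(f"ligand {record.id!r}: unparsable molecule")
    donors = sum(
        1
        for atom in mol.GetAtoms()
        if atom.GetSymbol() in ("N", "O") and atom.GetTotalNumHs() >= 1
    )
    return DescriptorBlock(
        molecular_weight=float(Descriptors.MolWt(mol)),
        logp=float(Crippen.MolLogP(mol)),
        hbond_donors=donors,
        hbond_acceptors=int(Lipinski.NOCount(mol)),
    )


def _descriptors_for(record: LigandRecord) -> DescriptorBlock:
    if record.has_descriptors:
        d = record.descriptors
        return DescriptorBlock(
            molecular_weight=float(d["molecular_weight"]),
            logp=float(d["logp"]),
            hbond_donors=int(d["hbond_donors"]),
            hbond_acceptors=int(d["hbond_acceptors"]),
        )
    return compute_descriptors(record)


def arg168_distance_filter(
    ligand_atoms: Sequence[Atom],
    receptor: Structure,
    chain_id: str,
    max_dist: float = 4.5,
    anchor_arg_resnum: int = 168,
) -> tuple[bool, float, str]:
    """Distance filtration against the anchor arginine.

    Measures the minimum distance from any carboxylate carbon of the ligand
    to the guanidinium carbon (CZ) of Arg168 and passes iff it does not
    exceed ``max_dist`` (inclusive).  Returns ``(flag, distance, reason)``;
    a ligand without a carboxyl carbon fails with reason
    ``"no carboxyl carbon"`` and a NaN distance.
    """
    cz = None
    for a in receptor.atoms:
        if (
            a.chain_id == chain_id
            and a.residue_name == "ARG"
            and a.residue_number == anchor_arg_resnum
            and a.name == "CZ"
        ):
            cz = a
            break
    if cz is None:
        raise ValueError(
            f"receptor chain {chain_id} lacks ARG {anchor_arg_resnum} atom CZ"
        )
    carbons = atoms_with_role(list(ligand_atoms), "carboxylate_carbon")
    if not carbons:
        return (False, float("nan"), "no carboxyl carbon")
    dist = min(float(np.linalg.norm(c.coords - cz.coords)) for c in carbons)
    return (dist <= max_dist, dist, "")


@dataclass
class ScreenConfig:
    """Configuration of the screening funnel.

    ``model_id`` 1 is the holo receptor (cofactor present; candidates compete
    with pyruvate, one loop interaction suffices); ``model_id`` 2 is the apo
    receptor (candidates must span both sub-sites, two loop interactions
    required).  ``min_loop_interactions`` may be set explicitly to override
    the model default.
    """

    receptor: Structure
    chain_id: str
    criteria: CriteriaTable
    model_id: int = 1
    arg168_carbon_max: float = 4.5
    min_loop_interactions: Optional[int] = None
    require_bidentate_arg168: bool = True
    cutoffs: GeometricCutoffs = field(default_factory=GeometricCutoffs)
    anchor_arg_resnum: int = 168

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2):
            raise ValueError("model_id must be 1 or 2")
        if self.min_loop_interactions is None:
            self.min_loop_interactions = 1 if self.model_id == 1 else 2
        if self.min_loop_interactions < 0:
            raise ValueError("min_loop_interactions must be >= 0")
        if self.arg168_carbon_max <= 0:
            raise ValueError("arg168_carbon_max must be positive")


@dataclass
class LigandOutcome:
    """Per-ligand audit through the funnel; stages not reached stay None."""

    ligand_id: str
    lipinski: Optional[bool] = None
    lipinski_violations: list[str] = field(default_factory=list)
    pose_present: Optional[bool] = None
    arg168_pass: Optional[bool] = None
    arg168_distance: float = float("nan")
    arg168_reason: str = ""
    bidentate: Optional[bool] = None
    loop_count: Optional[int] = None
    loop_pass: Optional[bool] = None
    selected: bool = False
    best_pose_index: Optional[int] = None
    fingerprint: Optional[Fingerprint] = None


@dataclass
class FunnelReport:
    """Full audit of a library run: per-ligand outcomes plus stage counts."""

    outcomes: list[LigandOutcome]
    survivor_counts: dict[str, int]
    config_summary: dict

    @property
    def selected_ids(self) -> list[str]:
        return [o.ligand_id for o in self.outcomes if o.selected]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.outcomes:
            rows.append(
                {
                    "ligand_id": o.ligand_id,
                    "lipinski": o.lipinski,
                    "lipinski_violations": ";".join(o.lipinski_violations),
                    "pose_present": o.pose_present,
                    "arg168_pass": o.arg168_pass,
                    "arg168_distance_A": (
                        round(o.arg168_distance, 2)
                        if math.isfinite(o.arg168_distance)
                        else ""
                    ),
                    "bidentate": o.bidentate,
                    "loop_count": o.loop_count,
                    "loop_pass": o.loop_pass,
                    "selected": o.selected,
                    "best_pose_index": o.best_pose_index,
                }
            )
        return pd.DataFrame(rows)


def _evaluate_pose(
    pose_atoms: Sequence[Atom], cfg: ScreenConfig, pose_id: str
) -> tuple[bool, float, str, bool, int, Fingerprint]:
    arg_pass, arg_dist, arg_reason = arg168_distance_filter(
        pose_atoms,
        cfg.receptor,
        cfg.chain_id,
        cfg.arg168_carbon_max,
        cfg.anchor_arg_resnum,
    )
    fp = fingerprint_pose(
        cfg.receptor,
        cfg.chain_id,
        pose_atoms,
        cfg.criteria,
        cfg.cutoffs,
        pose_id=pose_id,
        anchor_arg_resnum=cfg.anchor_arg_resnum,
    )
    return (
        arg_pass,
        arg_dist,
        arg_reason,
        fp.has_bidentate_arg168,
        fp.loop_interaction_count,
        fp,
    )


def run_funnel(
    library: Sequence[LigandRecord],
    poses: Mapping[str, Sequence[Sequence[Atom]]],
    cfg: ScreenConfig,
) -> FunnelReport:
    """Run every library member through the staged funnel.

    ``poses`` maps ligand id to its docked poses (each a list of atoms).  A
    pose referencing an unknown ligand id is an error; an empty library is an
    error.  The selected set and the full report are deterministic for fixed
    inputs.
    """
    if not library:
        raise ValueError("empty library")
    known = {r.id for r in library}
    if len(known) != len(library):
        raise ValueError("duplicate ligand ids in library")
    unknown = set(poses) - known
    if unknown:
        raise ValueError(f"poses reference unknown ligand ids: {sorted(unknown)}")

    outcomes: list[LigandOutcome] = []
    for record in library:
        out = LigandOutcome(ligand_id=record.id)
        outcomes.append(out)

        descriptors = _descriptors_for(record)
        out.lipinski, out.lipinski_violations = lipinski_pass(descriptors)
        if not out.lipinski:
            continue

        ligand_poses = list(poses.get(record.id, ()))
        out.pose_present = bool(ligand_poses)
        if not out.pose_present:
            continue

        evaluated = [
            _evaluate_pose(p, cfg, pose_id=f"{record.id}/{i}")
            for i, p in enumerate(ligand_poses)
        ]

        # ligand-level stage outcomes: any pose passing the stage and all
        # prior geometric stages
        arg_survivors = [
            (i, e) for i, e in enumerate(evaluated) if e[0]
        ]
        out.arg168_pass = bool(arg_survivors)
        finite = [e[1] for e in evaluated if math.isfinite(e[1])]
        out.arg168_distance = min(finite) if finite else float("nan")
        if not out.arg168_pass:
            out.arg168_reason = next(
                (e[2] for e in evaluated if e[2]), "distance exceeded"
            )
            continue

        bid_survivors = [(i, e) for i, e in arg_survivors if e[3]]
        out.bidentate = bool(bid_survivors) if cfg.require_bidentate_arg168 else True
        candidates = bid_survivors if cfg.require_bidentate_arg168 else arg_survivors
        if not out.bidentate:
            # report the best pose that reached this stage
            i, e = min(arg_survivors, key=lambda t: (t[1][1], -t[1][4], t[0]))
            out.best_pose_index, out.loop_count, out.fingerprint = i, e[4], e[5]
            continue

        loop_survivors = [
            (i, e) for i, e in candidates if e[4] >= cfg.min_loop_interactions
        ]
        pool = loop_survivors or candidates
        i, e = min(pool, key=lambda t: (t[1][1], -t[1][4], t[0]))
        out.best_pose_index = i
        out.loop_count = e[4]
        out.fingerprint = e[5]
        out.loop_pass = bool(loop_survivors)
        out.selected = out.loop_pass
    counts = {
        "intake": len(outcomes),
        "lipinski": sum(1 for o in outcomes if o.lipinski),
        "pose_present": sum(1 for o in outcomes if o.pose_present),
        "arg168_filter": sum(1 for o in outcomes if o.arg168_pass),
        "bidentate": sum(1 for o in outcomes if o.bidentate),
        "loop_criterion": sum(1 for o in outcomes if o.loop_pass),
        "selected": sum(1 for o in outcomes if o.selected),
    }
    config_summary = {
        "model_id": cfg.model_id,
        "arg168_carbon_max": cfg.arg168_carbon_max,
        "min_loop_interactions": cfg.min_loop_interactions,
        "require_bidentate_arg168": cfg.require_bidentate_arg168,
        "hbond_max": cfg.cutoffs.hbond_max,
        "hydrophobic_max": cfg.cutoffs.hydrophobic_max,
        "electrostatic_max": cfg.cutoffs.electrostatic_max,
    }
    return FunnelReport(outcomes=outcomes, survivor_counts=counts, config_summary=config_summary)


def write_report(report: FunnelReport, out_dir: str | Path, reproducible: bool = True) -> tuple[Path, Path]:
    """Write the per-ligand CSV and the JSON stage summary.

    Column order is stable; with ``reproducible=True`` (the default) no
    timestamp is embedded, so identical inputs give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "funnel_report.csv"
    json_path = out_dir / "funnel_summary.json"
    report.to_frame().to_csv(csv_path, index=False)
    summary = {
        "survivor_counts": report.survivor_counts,
        "selected_count": len(report.selected_ids),
        "selected_ids": report.selected_ids,
        "config": report.config_summary,
    }
    if not reproducible:
        import datetime

        summary["written_at"] = datetime.datetime.now().isoformat()
    json_path.write_text(json.dumps(summary, indent=2) + "\n")
    return csv_path, json_path
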