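"""Distances, rigid-body superposition, RMSD, and loop-ensemble analysis.

The mobile loop 96–111 caps the LDH-A active site; its open-state positions
vary between crystal forms and even between subunits of one tetramer, while
the closed state is essentially unique.  This module provides the machinery
used to quantify that: Kabsch superposition on Cα atoms, RMSD reported on a
chosen atom subset (typically the loop Cα), and the labelled contact-distance
tables that turn a bound-complex geometry into selection criteria.

Conventions
-----------
* Superposition minimises RMSD over proper rotations only (determinant +1);
  the reflection-optimal degenerate case is resolved by flipping the sign of
  the smallest singular vector.
* Pairwise loop RMSD between two ensemble members is computed after each is
  fitted to the common reference, not to each other.  A matrix built this way
  is symmetric with a zero diagonal but need not satisfy the triangle
  inequality — documented, not asserted.
* Distances are reported to 2 decimals in tables; full precision is kept
  internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .structure_io import Atom, AtomSelector, Structure, select_atoms

logger = logging.getLogger(__name__)

__all__ = [
    "RigidTransform",
    "DistanceSpec",
    "distance",
    "kabsch_fit",
    "rmsd",
    "ensemble_loop_analysis",
    "EnsembleReport",
    "measure_contact_table",
]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x ↦ R x + t (rotation 3×3, translation Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthogonal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-8):
            raise ValueError("rotation matrix is not proper (det != +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two points in Å."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(a - b))


def rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Root-mean-square deviation between paired coordinate sets, in Å.

    No fitting is performed — superposition is :func:`kabsch_fit`'s job.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3 or A.shape[0] < 1:
        raise ValueError(f"coordinate shape mismatch: {A.shape} vs {B.shape}")
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def kabsch_fit(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rigid motion minimising the RMSD between the
    transformed mobile coordinates and the reference, and the RMSD after the
    fit.  Uses the SVD of the cross-covariance of the centred point sets; if
    the optimal orthogonal matrix is a reflection, the sign of the singular
    vector belonging to the smallest singular value is flipped.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"length mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 paired 3-D points")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    P = mobile - mu_m
    Q = reference - mu_r
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    transform = RigidTransform(R, t)
    return transform, rmsd(transform.apply(mobile), reference)


def _coords(atoms: Sequence[Atom]) -> np.ndarray:
    return np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)


def _atom_map(atoms: Sequence[Atom]) -> dict[tuple[int, str, str], Atom]:
    """Correspondence key: (residue number, insertion code, atom name).

    Subunits are identical chains, so atoms correspond by author residue
    number and atom name; no sequence alignment is attempted.
    """
    return {(a.residue_number, a.insertion_code, a.name): a for a in atoms}


@dataclass
class EnsembleReport:
    """Result of :func:`ensemble_loop_analysis`.

    ``labels`` — one per subunit (``"<structure id>:<chain>"``);
    ``rmsd_to_reference`` — loop RMSD of each fitted subunit to the reference;
    ``pairwise`` — symmetric matrix of loop RMSDs between fitted subunits;
    ``errors`` — subunits dropped (fewer than 3 common fit atoms).
    """

    labels: list[str]
    rmsd_to_reference: np.ndarray
    pairwise: np.ndarray
    fit_atom_counts: list[int]
    report_atom_counts: list[int]
    errors: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.round(self.pairwise, 2), index=self.labels, columns=self.labels
        )


def ensemble_loop_analysis(
    structures: Sequence[tuple[Structure, str]],
    reference: tuple[Structure, str],
    fit_selector: AtomSelector,
    report_selector: AtomSelector,
) -> EnsembleReport:
    """Superpose each subunit onto a common reference and compare a region.

    Every subunit is independently fitted to the reference on the atoms picked
    by ``fit_selector`` (typically all Cα common to both chains) and RMSDs are
    then reported on ``report_selector`` atoms (typically loop 96–111 Cα).
    Missing residues reduce the fit/report sets to the pairwise-common subset,
    which is logged.  Subunits with fewer than 3 common fit atoms are recorded
    in ``errors`` and excluded from the matrices.
    """
    ref_structure, ref_chain = reference
    ref_sel = AtomSelector(
        chain_id=ref_chain,
        residue_range=fit_selector.residue_range,
        residue_names=fit_selector.residue_names,
        atom_names=fit_selector.atom_names,
        hetero_flag=fit_selector.hetero_flag,
    )
    ref_rep_sel = AtomSelector(
        chain_id=ref_chain,
        residue_range=report_selector.residue_range,
        residue_names=report_selector.residue_names,
        atom_names=report_selector.atom_names,
        hetero_flag=report_selector.hetero_flag,
    )
    ref_fit = _atom_map(select_atoms(ref_structure, ref_sel))
    ref_rep = _atom_map(select_atoms(ref_structure, ref_rep_sel))

    labels: list[str] = []
    fitted_report_coords: list[np.ndarray] = []
    report_keys: list[list[tuple[int, str, str]]] = []
    rmsd_to_ref: list[float] = []
    fit_counts: list[int] = []
    rep_counts: list[int] = []
    errors: dict[str, str] = {}

    for structure, chain in structures:
        label = f"{structure.id}:{chain}"
        sel = AtomSelector(
            chain_id=chain,
            residue_range=fit_selector.residue_range,
            residue_names=fit_selector.residue_names,
            atom_names=fit_selector.atom_names,
            hetero_flag=fit_selector.hetero_flag,
        )
        rep_sel = AtomSelector(
            chain_id=chain,
            residue_range=report_selector.residue_range,
            residue_names=report_selector.residue_names,
            atom_names=report_selector.atom_names,
            hetero_flag=report_selector.hetero_flag,
        )
        mob_fit = _atom_map(select_atoms(structure, sel))
        mob_rep = _atom_map(select_atoms(structure, rep_sel))
        common_fit = sorted(set(mob_fit) & set(ref_fit))
        if len(common_fit) < len(mob_fit) or len(common_fit) < len(ref_fit):
            logger.info(
                "%s: fitting on %d atoms common with reference", label, len(common_fit)
            )
        if len(common_fit) < 3:
            errors[label] = f"only {len(common_fit)} common fit atoms (need >= 3)"
            continue
        transform, _ = kabsch_fit(
            np.array([mob_fit[k].coords for k in common_fit]),
            np.array([ref_fit[k].coords for k in common_fit]),
        )
        common_rep = sorted(set(mob_rep) & set(ref_rep))
        if not common_rep:
            errors[label] = "no common report atoms"
            continue
        fitted = transform.apply(np.array([mob_rep[k].coords for k in common_rep]))
        ref_coords = np.array([ref_rep[k].coords for k in common_rep])
        labels.append(label)
        fitted_report_coords.append(fitted)
        report_keys.append(common_rep)
        rmsd_to_ref.append(rmsd(fitted, ref_coords))
        fit_counts.append(len(common_fit))
        rep_counts.append(len(common_rep))

    n = len(labels)
    pairwise = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            keys = sorted(set(report_keys[i]) & set(report_keys[j]))
            if not keys:
                value = float("nan")
            else:
                ci = {k: c for k, c in zip(report_keys[i], fitted_report_coords[i])}
                cj = {k: c for k, c in zip(report_keys[j], fitted_report_coords[j])}
                value = rmsd(
                    np.array([ci[k] for k in keys]), np.array([cj[k] for k in keys])
                )
            pairwise[i, j] = pairwise[j, i] = value
    return EnsembleReport(
        labels=labels,
        rmsd_to_reference=np.array(rmsd_to_ref),
        pairwise=pairwise,
        fit_atom_counts=fit_counts,
        report_atom_counts=rep_counts,
        errors=errors,
    )


# ---------------------------------------------------------------------------
# Contact-distance tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceSpec:
    """One labelled atom-pair (or atom-to-role) distance to measure.

    ``ligand_selector`` picks candidate partner atoms; with
    ``aggregation='min'`` the minimum distance over the matching atoms is
    reported, with ``'named-atom'`` the selector must resolve to exactly one
    atom.  ``ligand_role`` optionally restricts partner atoms to a chemical
    role (``carboxylate_oxygen``; resolved via
    :func:`pose_triage.interactions.find_carboxylate_groups`).
    """

    label: str
    receptor_selector: AtomSelector
    ligand_selector: AtomSelector
    aggregation: str = "named-atom"  # "min" | "named-atom"
    ligand_role: Optional[str] = None


def measure_contact_table(
    structure: Structure,
    chain_id: str,
    table: Sequence[DistanceSpec],
) -> pd.DataFrame:
    """Measure every labelled distance of ``table`` on one chain of ``structure``.

    Returns a DataFrame with columns ``label, receptor_atom, ligand_atom,
    distance_A`` (distances rounded to 2 decimals, the convention for printed
    contact tables).  A missing ligand partner flags the row ``absent``; a
    missing receptor atom is an error naming the spec label.
    """
    labels_seen = set()
    rows = []
    for spec in table:
        if spec.label in labels_seen:
            raise ValueError(f"duplicate table label {spec.label!r}")
        labels_seen.add(spec.label)
        rec_sel = spec.receptor_selector
        if rec_sel.chain_id is None:
            rec_sel = AtomSelector(
                chain_id=chain_id,
                residue_range=rec_sel.residue_range,
                residue_names=rec_sel.residue_names,
                atom_names=rec_sel.atom_names,
                hetero_flag=rec_sel.hetero_flag,
            )
        receptor_atoms = select_atoms(structure, rec_sel)
        if not receptor_atoms:
            raise ValueError(f"receptor atom not found for spec {spec.label!r}")
        lig_sel = spec.ligand_selector
        if lig_sel.chain_id is None and chain_id is not None:
            lig_sel = AtomSelector(
                chain_id=chain_id,
                residue_range=lig_sel.residue_range,
                residue_names=lig_sel.residue_names,
                atom_names=lig_sel.atom_names,
                hetero_flag=lig_sel.hetero_flag,
            )
        ligand_atoms = select_atoms(structure, lig_sel)
        if spec.ligand_role is not None:
            from .interactions import atoms_with_role

            ligand_atoms = atoms_with_role(ligand_atoms, spec.ligand_role)
        if not ligand_atoms:
            rows.append(
                {
                    "label": spec.label,
                    "receptor_atom": receptor_atoms[0].qualified_name,
                    "ligand_atom": None,
                    "distance_A": float("nan"),
                    "status": "absent",
                }
            )
            continue
        if spec.aggregation == "named-atom" and len(ligand_atoms) > 1:
            raise ValueError(
                f"spec {spec.label!r}: named-atom aggregation matched "
                f"{len(ligand_atoms)} ligand atoms"
            )
        best = None
        for r in receptor_atoms:
            for l in ligand_atoms:
                d = distance(r.coords, l.coords)
                if best is None or d < best[0]:
                    best = (d, r, l)
        d, r, l = best
        rows.append(
            {
                "label": spec.label,
                "receptor_atom": r.qualified_name,
                "ligand_atom": l.qualified_name,
                "distance_A": round(d, 2),
                "status": "ok",
            }
        )
    return pd.DataFrame(rows, columns=["label", "receptor_atom", "ligand_atom", "distance_A", "status"])
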