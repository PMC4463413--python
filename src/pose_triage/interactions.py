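"""Geometric protein–ligand interaction detection and fingerprinting.

Detects hydrogen bonds, hydrophobic contacts and electrostatic contacts
between a docked ligand pose and the receptor, recognises the bidentate
("twin") arginine–carboxylate salt bridge that anchors pyruvate-like ligands
to Arg168, and matches poses against a declarative criteria table whose rows
come from the contact geometry of closed-state LDH-A complexes.

All criteria are heavy-atom distance criteria.  Crystal structures and most
docking outputs carry no hydrogens, so by default a hydrogen bond is any
N/O···N/O pair within ``hbond_max``; when explicit hydrogens are present an
optional donor–H···acceptor angle check (≥ 120°) can be enabled.

Chemical roles on the ligand side (carboxylate oxygens, non-polar carbons,
phosphate) are resolved from connectivity when bonds can be inferred from
the geometry, with an atom-name fallback that logs a warning.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .structure_io import Atom, SOLVENT_RESNAMES, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "GeometricCutoffs",
    "Contact",
    "Criterion",
    "CriteriaTable",
    "Fingerprint",
    "BidentateResult",
    "detect_hbonds",
    "detect_hydrophobic",
    "detect_electrostatic",
    "detect_bidentate_arginine",
    "fingerprint_pose",
    "find_carboxylate_groups",
    "atoms_with_role",
    "parse_criteria_table",
]

#: Default loop boundaries (author numbering, inclusive): the mobile
#: active-site loop of LDH-A.
LOOP_RANGE = (96, 111)

GUANIDINIUM_NITROGENS = ("NE", "NH1", "NH2")


@dataclass(frozen=True)
class GeometricCutoffs:
    """Heavy-atom distance cutoffs, Å.

    Defaults are the smallest round conventional values that admit every
    contact observed in the closed-state reference complexes: hydrogen bonds
    up to 3.5 Å donor–acceptor, hydrophobic carbon–carbon contacts up to
    4.5 Å, charged-group contacts up to 4.5 Å.
    """

    hbond_max: float = 3.5
    hydrophobic_max: float = 4.5
    electrostatic_max: float = 4.5

    def __post_init__(self) -> None:
        if min(self.hbond_max, self.hydrophobic_max, self.electrostatic_max) <= 0:
            raise ValueError("cutoffs must be positive")
        if self.hbond_max >= self.hydrophobic_max:
            warnings.warn(
                "hbond_max >= hydrophobic_max is unusual", stacklevel=2
            )

    def for_kind(self, kind: str) -> float:
        return {
            "hbond": self.hbond_max,
            "hydrophobic": self.hydrophobic_max,
            "electrostatic": self.electrostatic_max,
        }[kind]


@dataclass(frozen=True)
class Contact:
    """One detected interaction between a receptor atom and a ligand atom."""

    kind: str  # hbond | hydrophobic | electrostatic
    receptor_atom: Atom
    ligand_atom: Atom
    distance: float
    matched_criterion: Optional[str] = None


# ---------------------------------------------------------------------------
# Connectivity inference and chemical roles
# ---------------------------------------------------------------------------

# Generous single-bond length ceilings for heavy-atom pairs; geometry-based
# bond perception only needs to separate bonded (~1.2-1.6 Å) from non-bonded
# (>2.2 Å) pairs.
_BOND_MAX_DEFAULT = 1.8
_BOND_MAX_WITH_P_OR_S = 2.0


def _bonded(a: Atom, b: Atom) -> bool:
    limit = (
        _BOND_MAX_WITH_P_OR_S
        if a.element in ("P", "S") or b.element in ("P", "S")
        else _BOND_MAX_DEFAULT
    )
    return float(np.linalg.norm(a.coords - b.coords)) <= limit


def infer_bonds(atoms: Sequence[Atom]) -> dict[int, list[int]]:
    """Distance-based bond perception among heavy atoms (indices into ``atoms``)."""
    adj: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
    for i, j in itertools.combinations(range(len(atoms)), 2):
        if atoms[i].element == "H" or atoms[j].element == "H":
            continue
        if _bonded(atoms[i], atoms[j]):
            adj[i].append(j)
            adj[j].append(i)
    return adj


def find_carboxylate_groups(atoms: Sequence[Atom]) -> list[tuple[Atom, list[Atom]]]:
    """Identify carboxylate groups: a carbon bonded to two oxygens that have
    no other heavy-atom neighbour besides that carbon.

    Returns ``[(carboxyl carbon, [O, O]), ...]``.  Falls back to an atom-name
    heuristic (oxygens named OXT/O1/O2/OE.../OD... grouped with the nearest
    carbon) only when no bond can be inferred at all, with a logged warning.
    """
    adj = infer_bonds(atoms)
    groups: list[tuple[Atom, list[Atom]]] = []
    for i, a in enumerate(atoms):
        if a.element != "C":
            continue
        oxygens = [
            j
            for j in adj[i]
            if atoms[j].element == "O" and all(k == i for k in adj[j])
        ]
        if len(oxygens) >= 2:
            groups.append((a, [atoms[j] for j in oxygens[:2]]))
    if groups or any(adj.values()):
        # connectivity was recoverable; trust it (possibly: no carboxylate)
        return groups
    # name-heuristic fallback: no bonds inferable from the geometry at all
    name_oxygens = [
        a
        for a in atoms
        if a.element == "O" and a.name.upper().rstrip("0123456789") in {"O", "OXT", "OC"}
    ]
    if len(name_oxygens) >= 2:
        carbons = [a for a in atoms if a.element == "C"]
        if carbons:
            o = name_oxygens[0]
            c = min(carbons, key=lambda x: float(np.linalg.norm(x.coords - o.coords)))
            logger.warning(
                "carboxylate identified by atom-name heuristic (no inferable bonds)"
            )
            return [(c, name_oxygens[:2])]
    return []


def _nonpolar_carbons(atoms: Sequence[Atom]) -> list[Atom]:
    """Carbons with no inferred bond to N or O (aliphatic/aromatic CH)."""
    adj = infer_bonds(atoms)
    out = []
    for i, a in enumerate(atoms):
        if a.element != "C":
            continue
        if any(atoms[j].element in ("N", "O") for j in adj[i]):
            continue
        out.append(a)
    return out


def atoms_with_role(atoms: Sequence[Atom], role: str) -> list[Atom]:
    """Resolve a chemical-role specifier to ligand atoms.

    Roles: ``polar`` (N or O), ``oxygen``, ``nitrogen``, ``carbon``,
    ``nonpolar_carbon``, ``carboxylate_oxygen``, ``carboxylate_carbon``,
    ``anion`` (carboxylate O plus phosphate P/O), ``phosphate``, ``any``.
    """
    atoms = [a for a in atoms if a.element != "H"]
    if role == "any":
        return list(atoms)
    if role == "polar":
        return [a for a in atoms if a.element in ("N", "O")]
    if role in ("oxygen", "nitrogen", "carbon"):
        symbol = {"oxygen": "O", "nitrogen": "N", "carbon": "C"}[role]
        return [a for a in atoms if a.element == symbol]
    if role == "nonpolar_carbon":
        return _nonpolar_carbons(atoms)
    if role == "carboxylate_oxygen":
        return [o for _, oxygens in find_carboxylate_groups(atoms) for o in oxygens]
    if role == "carboxylate_carbon":
        return [c for c, _ in find_carboxylate_groups(atoms)]
    if role == "phosphate":
        phosphorus = [a for a in atoms if a.element == "P"]
        adj = infer_bonds(atoms)
        index = {id(a): i for i, a in enumerate(atoms)}
        oxygens = [
            atoms[j]
            for p in phosphorus
            for j in adj[index[id(p)]]
            if atoms[j].element == "O"
        ]
        return phosphorus + oxygens
    if role == "anion":
        seen: dict[int, Atom] = {}
        for a in atoms_with_role(atoms, "carboxylate_oxygen") + atoms_with_role(
            atoms, "phosphate"
        ):
            seen.setdefault(id(a), a)
        return list(seen.values())
    raise ValueError(f"unknown chemical role {role!r}")


def _receptor_charged_atoms(atoms: Sequence[Atom]) -> tuple[list[Atom], list[Atom]]:
    """(positive, negative) charged-group heavy atoms on the receptor side."""
    positive, negative = [], []
    for a in atoms:
        if a.residue_name == "ARG" and a.name in GUANIDINIUM_NITROGENS:
            positive.append(a)
        elif a.residue_name == "LYS" and a.name == "NZ":
            positive.append(a)
        elif a.residue_name == "ASP" and a.name in ("OD1", "OD2"):
            negative.append(a)
        elif a.residue_name == "GLU" and a.name in ("OE1", "OE2"):
            negative.append(a)
    return positive, negative


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------


def _heavy(atoms: Sequence[Atom]) -> list[Atom]:
    return [a for a in atoms if a.element != "H" and a.residue_name not in SOLVENT_RESNAMES]


def _pairs_within(
    rec: Sequence[Atom], lig: Sequence[Atom], cutoff: float, kind: str
) -> list[Contact]:
    contacts = []
    for r in rec:
        for l in lig:
            d = float(np.linalg.norm(r.coords - l.coords))
            if d <= cutoff:
                contacts.append(Contact(kind, r, l, d))
    return contacts


def detect_hbonds(
    receptor_atoms: Sequence[Atom],
    ligand_atoms: Sequence[Atom],
    cutoffs: GeometricCutoffs = GeometricCutoffs(),
) -> list[Contact]:
    """All receptor-N/O to ligand-N/O pairs within ``hbond_max``.

    Heavy-atom criterion only: with crystallographic or docked heavy-atom
    coordinates the donor/acceptor distinction is not resolvable, so any
    short N/O···N/O pair counts.
    """
    rec = [a for a in _heavy(receptor_atoms) if a.element in ("N", "O")]
    lig = [a for a in _heavy(ligand_atoms) if a.element in ("N", "O")]
    return _pairs_within(rec, lig, cutoffs.hbond_max, "hbond")


def detect_hydrophobic(
    receptor_atoms: Sequence[Atom],
    ligand_atoms: Sequence[Atom],
    cutoffs: GeometricCutoffs = GeometricCutoffs(),
) -> list[Contact]:
    """Non-polar carbon to non-polar carbon pairs within ``hydrophobic_max``."""
    rec = _nonpolar_carbons(_heavy(receptor_atoms))
    lig = _nonpolar_carbons(_heavy(ligand_atoms))
    return _pairs_within(rec, lig, cutoffs.hydrophobic_max, "hydrophobic")


def detect_electrostatic(
    receptor_atoms: Sequence[Atom],
    ligand_atoms: Sequence[Atom],
    cutoffs: GeometricCutoffs = GeometricCutoffs(),
) -> list[Contact]:
    """Oppositely-charged group atoms within ``electrostatic_max``.

    Receptor charges come from side-chain identity (Arg/Lys positive,
    Asp/Glu negative); ligand anionic atoms are carboxylate oxygens and
    phosphate P/O resolved from connectivity.
    """
    rec_pos, rec_neg = _receptor_charged_atoms(_heavy(receptor_atoms))
    lig = _heavy(ligand_atoms)
    lig_neg = atoms_with_role(lig, "anion")
    contacts = _pairs_within(rec_pos, lig_neg, cutoffs.electrostatic_max, "electrostatic")
    # cationic ligand groups (e.g. guanidinium/ammonium N with no O neighbour)
    adj = infer_bonds(lig)
    lig_pos = [
        a
        for i, a in enumerate(lig)
        if a.element == "N" and not any(lig[j].element == "O" for j in adj[i])
    ]
    contacts += _pairs_within(rec_neg, lig_pos, cutoffs.electrostatic_max, "electrostatic")
    return contacts


@dataclass(frozen=True)
class BidentateResult:
    """Outcome of the twin arginine–carboxylate check."""

    is_bidentate: bool
    contacts: tuple[Contact, ...] = ()
    reason: str = ""

    def __bool__(self) -> bool:
        return self.is_bidentate


def detect_bidentate_arginine(
    arg_atoms: Sequence[Atom],
    ligand_atoms: Sequence[Atom],
    cutoffs: GeometricCutoffs = GeometricCutoffs(),
) -> BidentateResult:
    """Recognise a bidentate salt bridge between an arginine guanidinium and a
    ligand carboxylate.

    True iff two *distinct* guanidinium nitrogens (NE/NH1/NH2) are each within
    ``hbond_max`` of two *distinct* oxygens of one carboxylate group.  A single
    oxygen bridging both nitrogens does not qualify.  A ligand without a
    carboxylate returns ``reason='no carboxylate'`` so chemistry failures are
    distinguishable from geometric ones.
    """
    nitrogens = [a for a in arg_atoms if a.name in GUANIDINIUM_NITROGENS]
    if len(nitrogens) < 2:
        raise ValueError("arginine residue lacks guanidinium nitrogens (NE/NH1/NH2)")
    groups = find_carboxylate_groups(_heavy(ligand_atoms))
    if not groups:
        return BidentateResult(False, reason="no carboxylate")
    for _, oxygens in groups:
        o1, o2 = oxygens[0], oxygens[1]
        for n1, n2 in itertools.permutations(nitrogens, 2):
            d1 = float(np.linalg.norm(n1.coords - o1.coords))
            d2 = float(np.linalg.norm(n2.coords - o2.coords))
            if d1 <= cutoffs.hbond_max and d2 <= cutoffs.hbond_max:
                return BidentateResult(
                    True,
                    contacts=(
                        Contact("hbond", n1, o1, d1),
                        Contact("hbond", n2, o2, d2),
                    ),
                )
    return BidentateResult(False, reason="geometry")


# ---------------------------------------------------------------------------
# Criteria tables and fingerprints
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Criterion:
    """One named interaction criterion from the selection table.

    ``receptor_atom`` is ``"chain:resname:resnum:atom"`` (chain may be ``*``
    to mean the fingerprinted chain); ``ligand_role`` is a chemical-role
    specifier understood by :func:`atoms_with_role`.
    """

    label: str
    kind: str  # hbond | hydrophobic | electrostatic
    receptor_atom: str
    ligand_role: str
    cutoff: Optional[float] = None
    loop_member: bool = False

    def receptor_parts(self) -> tuple[str, str, int, str]:
        chain, resname, resnum, atom = self.receptor_atom.split(":")
        return chain, resname, int(resnum), atom


@dataclass
class CriteriaTable:
    """Declarative list of interaction criteria with unique labels.

    The ``loop_member`` flag of each entry must agree with ``loop_range``
    (a receptor residue inside the range is a loop criterion).
    """

    entries: list[Criterion]
    loop_range: tuple[int, int] = LOOP_RANGE

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(labels) != len(set(labels)):
            raise ValueError("criteria labels must be unique")
        lo, hi = self.loop_range
        for e in self.entries:
            resnum = e.receptor_parts()[2]
            if e.loop_member != (lo <= resnum <= hi):
                raise ValueError(
                    f"criterion {e.label!r}: loop_member flag inconsistent with "
                    f"residue {resnum} vs loop {self.loop_range}"
                )

    def loop_entries(self) -> list[Criterion]:
        return [e for e in self.entries if e.loop_member]


def parse_criteria_table(text: str, loop_range: tuple[int, int] = LOOP_RANGE) -> CriteriaTable:
    """Parse a criteria config: one entry per non-comment line.

    Format: ``label  kind  chain:resname:resnum:atom  ligand_role  [cutoff]``.
    """
    entries = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) not in (4, 5):
            raise ValueError(f"criteria line {lineno}: expected 4-5 fields")
        label, kind, receptor, role = parts[:4]
        if kind not in ("hbond", "hydrophobic", "electrostatic"):
            raise ValueError(f"criteria line {lineno}: unknown kind {kind!r}")
        cutoff = float(parts[4]) if len(parts) == 5 else None
        resnum = int(receptor.split(":")[2])
        entries.append(
            Criterion(
                label=label,
                kind=kind,
                receptor_atom=receptor,
                ligand_role=role,
                cutoff=cutoff,
                loop_member=loop_range[0] <= resnum <= loop_range[1],
            )
        )
    return CriteriaTable(entries=entries, loop_range=loop_range)


def format_criteria_table(table: CriteriaTable) -> str:
    """Inverse of :func:`parse_criteria_table`."""
    lines = ["# label kind receptor(chain:resname:resnum:atom) ligand_role [cutoff]"]
    for e in table.entries:
        line = f"{e.label} {e.kind} {e.receptor_atom} {e.ligand_role}"
        if e.cutoff is not None:
            line += f" {e.cutoff:g}"
        lines.append(line)
    return "\n".join(lines) + "\n"


@dataclass
class Fingerprint:
    """Interaction fingerprint of one pose against a criteria table.

    ``loop_interaction_count`` counts distinct satisfied criteria whose
    receptor residue lies on the mobile loop — criteria, not atom pairs, so
    duplicated ligand atoms never inflate it.
    """

    pose_id: str
    contacts: list[Contact]
    satisfied: dict[str, bool]
    unresolvable: list[str]
    loop_interaction_count: int
    has_bidentate_arg168: bool
    bidentate: BidentateResult


def _resolve_receptor_atom(
    receptor: Structure, chain_id: str, criterion: Criterion
) -> Optional[Atom]:
    chain, resname, resnum, atom_name = criterion.receptor_parts()
    if chain == "*":
        chain = chain_id
    for a in receptor.atoms:
        if (
            a.chain_id == chain
            and a.residue_number == resnum
            and a.name == atom_name
            and (resname == "*" or a.residue_name == resname)
        ):
            return a
    return None


def fingerprint_pose(
    receptor: Structure,
    chain_id: str,
    ligand_atoms: Sequence[Atom],
    criteria: CriteriaTable,
    cutoffs: GeometricCutoffs = GeometricCutoffs(),
    pose_id: str = "",
    anchor_arg_resnum: int = 168,
) -> Fingerprint:
    """Fingerprint one docked pose against the criteria table.

    Runs all three detectors on the heavy atoms of the given receptor chain
    (solvent excluded), marks each criterion satisfied or unsatisfied using
    its own cutoff override (else the kind default), counts distinct
    satisfied loop criteria, and checks the bidentate salt bridge to the
    anchor arginine (Arg168 by default).  A criterion whose receptor atom is
    missing is reported ``unresolvable`` and excluded from the count.
    """
    receptor_atoms = _heavy(
        [a for a in receptor.atoms if a.chain_id == chain_id]
    )
    ligand_heavy = _heavy(ligand_atoms)

    contacts = (
        detect_hbonds(receptor_atoms, ligand_heavy, cutoffs)
        + detect_hydrophobic(receptor_atoms, ligand_heavy, cutoffs)
        + detect_electrostatic(receptor_atoms, ligand_heavy, cutoffs)
    )

    satisfied: dict[str, bool] = {}
    unresolvable: list[str] = []
    annotated: list[Contact] = list(contacts)
    for criterion in criteria.entries:
        receptor_atom = _resolve_receptor_atom(receptor, chain_id, criterion)
        if receptor_atom is None:
            unresolvable.append(criterion.label)
            logger.warning(
                "criterion %r: receptor atom %s not found",
                criterion.label,
                criterion.receptor_atom,
            )
            continue
        cutoff = criterion.cutoff if criterion.cutoff is not None else cutoffs.for_kind(criterion.kind)
        candidates = atoms_with_role(ligand_heavy, criterion.ligand_role)
        hit = None
        for cand in candidates:
            d = float(np.linalg.norm(receptor_atom.coords - cand.coords))
            if d <= cutoff and (hit is None or d < hit[0]):
                hit = (d, cand)
        satisfied[criterion.label] = hit is not None
        if hit is not None:
            annotated.append(
                Contact(criterion.kind, receptor_atom, hit[1], hit[0], criterion.label)
            )

    loop_labels = {e.label for e in criteria.loop_entries()}
    loop_count = sum(
        1 for label, ok in satisfied.items() if ok and label in loop_labels
    )

    arg_atoms = [
        a
        for a in receptor_atoms
        if a.residue_name == "ARG" and a.residue_number == anchor_arg_resnum
    ]
    if arg_atoms:
        bidentate = detect_bidentate_arginine(arg_atoms, ligand_heavy, cutoffs)
    else:
        bidentate = BidentateResult(False, reason=f"no ARG {anchor_arg_resnum} in chain {chain_id}")

    return Fingerprint(
        pose_id=pose_id,
        contacts=annotated,
        satisfied=satisfied,
        unresolvable=unresolvable,
        loop_interaction_count=loop_count,
        has_bidentate_arg168=bidentate.is_bidentate,
        bidentate=bidentate,
    )
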