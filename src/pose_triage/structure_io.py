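"""Read/write macromolecular structures and ligand libraries.

The structural inputs of the triage pipeline are plain PDB files: a receptor
(an LDH-A subunit or a synthetic active-site fragment) plus hetero groups
(oxamate, NADH, docked poses).  This module parses them into a flat,
deterministic atom model, provides the atom-selection mini-grammar used by
every downstream stage (``chain=A resi=96-111 name=CA``), and reads small-
molecule libraries from SMILES or SD files via RDKit.

Only the first MODEL of a multi-model file is read.  Alternate locations
follow the single-conformer convention: blank or 'A' altlocs are kept, all
others dropped.  Hydrogens are retained when present, but all default
geometric criteria downstream operate on heavy atoms only.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Structure",
    "AtomSelector",
    "LigandRecord",
    "ParseError",
    "SelectionError",
    "parse_structure",
    "write_structure",
    "select_atoms",
    "parse_selector",
    "read_ligand_library",
]

#: Hetero residue codes normalised to a single internal label.  PDB entries
#: use several codes for the reduced nicotinamide cofactor.
NADH_ALIASES = {"NAI", "NAD", "NDH"}
NADH_LABEL = "NAI"

#: Residue names treated as solvent/ions: parsed, but excluded from
#: interaction detection by default.
SOLVENT_RESNAMES = {"HOH", "WAT", "DOD", "CL", "NA", "K", "MG", "ZN", "SO4"}


class ParseError(ValueError):
    """Raised when a structure or library stream cannot be parsed."""


class SelectionError(ValueError):
    """Raised for contradictory atom selectors (e.g. residue range lo > hi)."""


@dataclass(frozen=True)
class Atom:
    """One ATOM/HETATM record with author numbering preserved exactly."""

    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    altloc: str = ""
    residue_name: str = ""
    residue_number: int = 0
    insertion_code: str = ""
    chain_id: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coords", np.asarray(self.coords, dtype=float).reshape(3)
        )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not self.name:
            raise ValueError("atom name must be non-empty")

    @property
    def residue_key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_number, self.insertion_code, self.residue_name)

    @property
    def qualified_name(self) -> str:
        """``A:ARG:105:NH2`` — the receptor-atom notation used in criteria tables."""
        return f"{self.chain_id}:{self.residue_name}:{self.residue_number}:{self.name}"

    def moved_to(self, coords: np.ndarray) -> "Atom":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class Structure:
    """A parsed structure: an ordered list of atoms with a stable identity.

    Atom order is file order and is the iteration order everywhere; the tuple
    (chain_id, residue_number, insertion_code, atom_name, altloc) addresses an
    atom uniquely.
    """

    id: str
    atoms: list[Atom] = field(default_factory=list)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id)
        return list(seen)

    def residues(self) -> list[tuple[tuple[str, int, str, str], list[Atom]]]:
        """Atoms grouped by residue, in file order."""
        groups: dict[tuple[str, int, str, str], list[Atom]] = {}
        for a in self.atoms:
            groups.setdefault(a.residue_key, []).append(a)
        return list(groups.items())

    def hetero_records(self) -> dict[str, list[Atom]]:
        """Hetero atoms grouped by residue name (OXM, NAI, 88N, HOH, ...)."""
        out: dict[str, list[Atom]] = {}
        for a in self.atoms:
            if a.is_hetero:
                out.setdefault(a.residue_name, []).append(a)
        return out

    def find_atom(
        self, chain_id: str, residue_number: int, atom_name: str
    ) -> Optional[Atom]:
        for a in self.atoms:
            if (
                a.chain_id == chain_id
                and a.residue_number == residue_number
                and a.name == atom_name
            ):
                return a
        return None


@dataclass(frozen=True)
class AtomSelector:
    """Declarative atom filter; an empty selector selects every atom.

    ``residue_range`` is inclusive on both ends in author numbering, so the
    mobile loop is ``residue_range=(96, 111)`` — 16 residues.
    """

    chain_id: Optional[str] = None
    residue_range: Optional[tuple[int, int]] = None
    residue_names: Optional[frozenset[str]] = None
    atom_names: Optional[frozenset[str]] = None
    hetero_flag: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.residue_names is not None:
            object.__setattr__(self, "residue_names", frozenset(self.residue_names))
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", frozenset(self.atom_names))
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if lo > hi:
                raise SelectionError(f"residue_range lo > hi: {lo} > {hi}")

    def matches(self, atom: Atom) -> bool:
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not (lo <= atom.residue_number <= hi):
                return False
        if self.residue_names is not None and atom.residue_name not in self.residue_names:
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        if self.hetero_flag is not None and atom.is_hetero != self.hetero_flag:
            return False
        return True


def parse_selector(text: str) -> AtomSelector:
    """Parse the CLI mini-grammar, e.g. ``"chain=A resi=96-111 name=CA"``.

    Keys: ``chain``, ``resi`` (single number or lo-hi range), ``resn``
    (comma-separated residue names), ``name`` (comma-separated atom names),
    ``hetero`` (true/false).  An empty string selects all atoms.
    """
    kwargs: dict = {}
    for token in text.split():
        if "=" not in token:
            raise SelectionError(f"bad selector token {token!r} (expected key=value)")
        key, value = token.split("=", 1)
        if key == "chain":
            kwargs["chain_id"] = value
        elif key == "resi":
            if "-" in value[1:]:  # allow a leading minus on lo
                split_at = value.index("-", 1)
                lo, hi = int(value[:split_at]), int(value[split_at + 1 :])
            else:
                lo = hi = int(value)
            kwargs["residue_range"] = (lo, hi)
        elif key == "resn":
            kwargs["residue_names"] = frozenset(value.split(","))
        elif key == "name":
            kwargs["atom_names"] = frozenset(value.split(","))
        elif key == "hetero":
            kwargs["hetero_flag"] = value.lower() in {"1", "true", "yes"}
        else:
            raise SelectionError(f"unknown selector key {key!r}")
    return AtomSelector(**kwargs)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_KEPT_ALTLOCS = {"", " ", "A", "\x00"}


def _validate_coordinate_columns(text: str) -> None:
    # gemmi zero-fills unparsable coordinate fields instead of failing, so
    # malformed input must be caught before it reaches the parser.
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ParseError(
                        f"malformed coordinate field on line {lineno}: "
                        f"{line[lo:hi].strip()!r}"
                    ) from None


def parse_structure(text: str, structure_id: str = "") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Every ATOM/HETATM record of the first MODEL becomes exactly one
    :class:`Atom`; insertion codes stay part of residue identity; author
    residue numbers are preserved verbatim.  NADH hetero codes (NAI/NAD/NDH)
    are normalised to one internal label.  Altlocs other than blank/'A' are
    dropped.
    """
    if not text.strip():
        raise ParseError("no atoms: empty input")
    _validate_coordinate_columns(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the line itself
        raise ParseError(str(exc)) from exc
    if len(st) == 0:
        raise ParseError("no atoms")
    if not structure_id:
        structure_id = st.name.lower() if st.name else "structure"
    atoms: list[Atom] = []
    model = st[0]  # MODEL blocks beyond the first are ignored
    for chain in model:
        for residue in chain:
            resname = residue.name.strip()
            if resname in NADH_ALIASES:
                resname = NADH_LABEL
            is_het = residue.het_flag == "H"
            for a in residue:
                altloc = a.altloc if a.altloc not in ("\x00", " ") else ""
                if altloc not in _KEPT_ALTLOCS:
                    continue
                atoms.append(
                    Atom(
                        name=a.name.strip(),
                        element=a.element.name,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        altloc=altloc,
                        residue_name=resname,
                        residue_number=residue.seqid.num,
                        insertion_code=(residue.seqid.icode or "").strip(),
                        chain_id=chain.name,
                        is_hetero=is_het,
                    )
                )
    if not atoms:
        raise ParseError("no atoms")
    return Structure(id=structure_id, atoms=atoms)


def write_structure(structure: Structure) -> str:
    """Serialise a :class:`Structure` to PDB-format text (fixed columns).

    Round-trip guarantee: ``parse_structure(write_structure(s))`` preserves
    atom count, names and coordinates to 3 decimals.
    """
    lines = []
    serial = 0
    for a in structure.atoms:
        serial += 1
        record = "HETATM" if a.is_hetero else "ATOM  "
        # PDB atom-name alignment: 1–2 char element names start in column 13
        name = a.name
        if len(name) < 4 and len(a.element) < 2:
            name = " " + name
        lines.append(
            f"{record}{serial:>5} {name:<4}{a.altloc or ' ':1}{a.residue_name:>3} "
            f"{a.chain_id:1}{a.residue_number:>4}{a.insertion_code or ' ':1}   "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def select_atoms(structure: Structure, selector: AtomSelector) -> list[Atom]:
    """Return the atoms matching every populated selector field, in file order.

    A selector matching zero atoms returns an empty list (not an error).
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    return [a for a in structure.atoms if selector.matches(a)]


# ---------------------------------------------------------------------------
# Docked-pose files
# ---------------------------------------------------------------------------
#
# Docked poses travel as plain PDB HETATM blocks, one block per pose, each
# preceded by a ``REMARK POSE <ligand id> <pose index>`` line.  The format is
# deliberately minimal: poses are consumed, never generated, and only the
# elements and coordinates matter to the geometric filters.


def write_pose_file(poses: "dict[str, list[list[Atom]]]") -> str:
    """Serialise poses (ligand id → list of poses) to REMARK-delimited PDB text."""
    chunks = []
    for lig_id in poses:
        for idx, pose in enumerate(poses[lig_id]):
            chunks.append(f"REMARK POSE {lig_id} {idx}")
            block = write_structure(Structure(id=lig_id, atoms=list(pose)))
            chunks.append(block.rsplit("END", 1)[0].rstrip())
    return "\n".join(chunks) + "\nEND\n"


def read_pose_file(text: str) -> dict[str, list[list[Atom]]]:
    """Inverse of :func:`write_pose_file`."""
    poses: dict[str, list[list[Atom]]] = {}
    current_id = None
    block: list[str] = []

    def flush() -> None:
        if current_id is not None and block:
            atoms = parse_structure("\n".join(block) + "\nEND\n", current_id).atoms
            poses.setdefault(current_id, []).append(atoms)

    for line in text.splitlines():
        if line.startswith("REMARK POSE"):
            flush()
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"bad pose header: {line!r}")
            current_id = parts[2]
            block = []
        elif line.startswith(("ATOM  ", "HETATM")):
            if current_id is None:
                raise ParseError("atom record before any REMARK POSE header")
            block.append(line)
    flush()
    if not poses:
        raise ParseError("no poses found")
    return poses


# ---------------------------------------------------------------------------
# Ligand libraries
# ---------------------------------------------------------------------------


@dataclass
class LigandRecord:
    """One library entry: identifier, connectivity, optional descriptors.

    ``descriptors`` maps ``molecular_weight / logp / hbond_donors /
    hbond_acceptors`` to values taken from SD tags when present; missing
    descriptors are computed later by :func:`pose_triage.screening.compute_descriptors`.
    """

    id: str
    smiles: str = ""
    mol: object = None  # rdkit Mol when available
    descriptors: dict = field(default_factory=dict)

    @property
    def has_descriptors(self) -> bool:
        return all(
            k in self.descriptors
            for k in ("molecular_weight", "logp", "hbond_donors", "hbond_acceptors")
        )


_SD_TAG_MAP = {
    "MW": "molecular_weight",
    "MOLECULAR_WEIGHT": "molecular_weight",
    "LOGP": "logp",
    "HBD": "hbond_donors",
    "HBA": "hbond_acceptors",
}


def read_ligand_library(text: str, fmt: str = "smi") -> list[LigandRecord]:
    """Read a small-molecule library from SMILES (``fmt='smi'``) or SD text.

    SMILES files are one molecule per line: ``SMILES  identifier`` (identifier
    optional; falls back to ``mol<N>``).  Unparsable records are skipped with a
    logged warning; zero valid records is an error.
    """
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    records: list[LigandRecord] = []
    skipped = 0
    if fmt == "smi":
        for i, line in enumerate(text.splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            lig_id = parts[1] if len(parts) > 1 else f"mol{i + 1}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                logger.warning("skipping unparsable SMILES record %r", lig_id)
                skipped += 1
                continue
            records.append(LigandRecord(id=lig_id, smiles=smiles, mol=mol))
    elif fmt in {"sdf", "sd"}:
        supplier = Chem.ForwardSDMolSupplier(io.BytesIO(text.encode()), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("skipping unparsable SD record #%d", i + 1)
                skipped += 1
                continue
            lig_id = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
            lig_id = lig_id or f"mol{i + 1}"
            descriptors = {}
            for tag, key in _SD_TAG_MAP.items():
                if mol.HasProp(tag):
                    value = float(mol.GetProp(tag))
                    descriptors[key] = int(value) if key.startswith("hbond") else value
            records.append(
                LigandRecord(
                    id=lig_id,
                    smiles=Chem.MolToSmiles(mol),
                    mol=mol,
                    descriptors=descriptors,
                )
            )
    else:
        raise ValueError(f"unknown library format {fmt!r} (expected 'smi' or 'sdf')")
    if not records:
        raise ParseError(f"zero valid ligand records ({skipped} skipped)")
    if skipped:
        logger.warning("%d unparsable records skipped", skipped)
    return records
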