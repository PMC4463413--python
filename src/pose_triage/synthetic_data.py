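"""Synthetic fixtures with planted, analytically known outcomes.

Real inputs to the triage pipeline are crystal structures and commercial
compound libraries that cannot ship with the package.  This module builds
small stand-ins that preserve exactly the geometric and statistical structure
the pipeline assumes, so every stage is testable with no download:

* an active-site fragment with an Arg168-analog guanidinium, loop-residue
  analogs (Ala97/Arg98/Gln99/Arg105) and a matching criteria table;
* reference bound complexes whose labelled contact distances equal the
  closed-state values observed in the oxamate and 88N co-crystal geometries;
* carboxylate-bearing ligand poses placed so that each filter's pass/fail
  outcome is known by construction;
* loop-conformer ensembles whose RMSDs have closed-form expected values;
* a descriptor-annotated compound library with a planted stage-failure plan
  and a manifest that fully determines the expected funnel output.

Planted distances are realised by exact geometric construction (direct
offsets, sphere–sphere intersections and two-anchor rigid placement) and are
then verified at generation time by running the pipeline's own detectors; a
request that cannot be realised raises :class:`InfeasiblePoseError`.  All
randomness is confined to nuisance degrees of freedom (spin angles, decoy
atoms, group shuffling) and comes from one explicitly seeded generator, so a
given seed reproduces every file byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import DistanceSpec
from .interactions import (
    CriteriaTable,
    Criterion,
    GeometricCutoffs,
    detect_bidentate_arginine,
    fingerprint_pose,
)
from .screening import arg168_distance_filter
from .structure_io import Atom, AtomSelector, LigandRecord, Structure

__all__ = [
    "InfeasiblePoseError",
    "PoseSpec",
    "StageFailurePlan",
    "FixtureManifest",
    "FUNNEL83_PLAN",
    "OPEN_LOOP_PAIR_RMSD",
    "CRITERIA_LABELS",
    "make_active_site",
    "plant_pose",
    "make_library",
    "make_loop_ensemble",
    "make_reference_complex",
    "OXAMATE_COMPLEX_CONTACTS",
    "INHIBITOR_88N_COMPLEX_CONTACTS",
]


class InfeasiblePoseError(ValueError):
    """A requested pose outcome combination cannot be realised geometrically."""


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise ValueError("zero vector")
    return v / n


def _perp(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to v."""
    v = _unit(v)
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(v, ref))


def _rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a onto unit vector b."""
    a, b = _unit(a), _unit(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        p = _perp(a)  # 180 degrees about any perpendicular axis
        return 2.0 * np.outer(p, p) - np.eye(3)
    K = np.array(
        [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]], dtype=float
    )
    return np.eye(3) + K + K @ K / (1.0 + c)


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]],
        dtype=float,
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _sphere_sphere_point(
    c1: np.ndarray,
    r1: float,
    c2: np.ndarray,
    r2: float,
    prefer: np.ndarray,
) -> np.ndarray:
    """A point at exactly r1 from c1 and r2 from c2, on the side of ``prefer``."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    d = float(np.linalg.norm(c2 - c1))
    if not (abs(r1 - r2) <= d <= r1 + r2):
        raise InfeasiblePoseError(
            f"spheres (r={r1:.2f}, r={r2:.2f}) at separation {d:.2f} do not intersect"
        )
    n = _unit(c2 - c1)
    a = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    center = c1 + a * n
    rho = math.sqrt(max(r1 * r1 - a * a, 0.0))
    w = np.asarray(prefer, dtype=float) - center
    w = w - np.dot(w, n) * n
    if np.linalg.norm(w) < 1e-9:
        w = _perp(n)
    return center + rho * _unit(w)


# ---------------------------------------------------------------------------
# Residue templates (idealised local coordinates, Å)
# ---------------------------------------------------------------------------

# Guanidinium: planar, C-N 1.33 Å, N-CZ-N 120 degrees; "mouth" (the NH1/NH2
# side that chelates a carboxylate) points along +x.
_GUANIDINIUM = {
    "CZ": np.array([0.0, 0.0, 0.0]),
    "NE": np.array([-1.33, 0.0, 0.0]),
    "NH1": np.array([0.665, 1.15182, 0.0]),
    "NH2": np.array([0.665, -1.15182, 0.0]),
}

_ARG_TEMPLATE = {
    **_GUANIDINIUM,
    "CD": np.array([-2.06, 1.264, 0.0]),
    "CG": np.array([-3.43, 0.58, 0.0]),
    "CB": np.array([-4.80, 1.26, 0.0]),
    "CA": np.array([-6.17, 0.58, 0.0]),
    "N": np.array([-6.73, 1.93, 0.0]),
    "C": np.array([-7.20, -0.50, 0.0]),
    "O": np.array([-6.90, -1.67, 0.0]),
}

_ALA_TEMPLATE = {
    "N": np.array([-0.56, 1.35, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "CB": np.array([-0.51, -1.44, 0.0]),
    "C": np.array([1.52, 0.0, 0.0]),
    "O": np.array([2.13, -1.07, 0.0]),
}

_GLN_TEMPLATE = {
    "N": np.array([-0.56, 1.35, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.52, 0.0, 0.0]),
    "O": np.array([2.10, 1.08, 0.0]),
    "CB": np.array([-0.51, -1.44, 0.0]),
    "CG": np.array([-2.04, -1.44, 0.0]),
    "CD": np.array([-2.55, -2.88, 0.0]),
    "OE1": np.array([-1.78, -3.82, 0.0]),
    "NE2": np.array([-3.88, -3.08, 0.0]),
}

_TEMPLATES = {"ARG": _ARG_TEMPLATE, "ALA": _ALA_TEMPLATE, "GLN": _GLN_TEMPLATE}


def _element_of(atom_name: str) -> str:
    return atom_name.strip("0123456789'")[:1]


def _make_residue_atoms(
    resname: str,
    resnum: int,
    placed: dict[str, np.ndarray],
    chain_id: str = "A",
    hetero: bool = False,
) -> list[Atom]:
    return [
        Atom(
            name=name,
            element=_element_of(name),
            coords=coords,
            residue_name=resname,
            residue_number=resnum,
            chain_id=chain_id,
            is_hetero=hetero,
        )
        for name, coords in placed.items()
    ]


def _place_template(
    template: dict[str, np.ndarray],
    probe: str,
    target: np.ndarray,
    outward: np.ndarray,
    spin: float = 0.0,
) -> dict[str, np.ndarray]:
    """Rigidly place a residue template with ``probe`` at ``target`` and the
    residue body pointing along ``outward``; ``spin`` turns about that axis."""
    body = np.mean(list(template.values()), axis=0) - template[probe]
    R = _rotation_aligning(body, outward)
    R = _axis_rotation(outward, spin) @ R
    return {
        name: target + R @ (coords - template[probe])
        for name, coords in template.items()
    }


def _place_two_anchor(
    template: dict[str, np.ndarray],
    anchor_a: str,
    anchor_b: str,
    target_a: np.ndarray,
    target_b: np.ndarray,
    avoid: Sequence[np.ndarray],
    n_spin: int = 72,
) -> dict[str, np.ndarray]:
    """Rigidly place a template so two named atoms land exactly on two targets
    (their separations must match); the free spin about the anchor axis is
    chosen to maximise the clearance of the remaining atoms from ``avoid``."""
    a_l, b_l = template[anchor_a], template[anchor_b]
    sep_l = float(np.linalg.norm(b_l - a_l))
    sep_w = float(np.linalg.norm(target_b - target_a))
    if abs(sep_l - sep_w) > 1e-6:
        raise InfeasiblePoseError(
            f"anchor separation mismatch: template {sep_l:.4f} vs target {sep_w:.4f}"
        )
    axis = _unit(target_b - target_a)
    R0 = _rotation_aligning(b_l - a_l, target_b - target_a)

    def placed_at(theta: float) -> dict[str, np.ndarray]:
        R = _axis_rotation(axis, theta) @ R0
        return {n: target_a + R @ (c - a_l) for n, c in template.items()}

    best, best_clearance = None, -1.0
    others = [n for n in template if n not in (anchor_a, anchor_b)]
    for k in range(n_spin):
        theta = 2 * math.pi * k / n_spin
        cand = placed_at(theta)
        if avoid and others:
            clearance = min(
                float(np.linalg.norm(cand[n] - p)) for n in others for p in avoid
            )
        else:
            clearance = 1.0
        if clearance > best_clearance:
            best, best_clearance = cand, clearance
    return best


# ---------------------------------------------------------------------------
# Active site and criteria table
# ---------------------------------------------------------------------------

#: Labels of the default criteria table (all six sit on the mobile loop).
CRITERIA_LABELS = (
    "ala97_hb",
    "arg98_cb_hydrophobic",
    "arg98_electrostatic",
    "gln99_hb",
    "arg105_hb1",
    "arg105_hb2",
)

# Interaction-centre layout: residues sit >= 9 Å apart so a ligand atom
# planted within cutoff of one criterion atom cannot satisfy another
# residue's criterion.
_SITE_LAYOUT = {
    97: (np.array([0.0, 0.0, 0.0]), np.array([-1.0, -1.0, 0.2])),
    98: (np.array([10.0, 0.0, 0.0]), np.array([1.0, -1.0, 0.1])),
    99: (np.array([0.0, 10.0, 0.0]), np.array([-1.0, 1.0, 0.1])),
    105: (np.array([10.0, 10.0, 0.0]), np.array([1.0, 1.0, 0.2])),
    168: (np.array([5.0, 5.0, 12.0]), np.array([0.0, 0.0, 1.0])),
}

_SITE_RESIDUES = {97: ("ALA", "O"), 98: ("ARG", "CB"), 99: ("GLN", "NE2"),
                  105: ("ARG", "NH2"), 168: ("ARG", "CZ")}


def default_criteria_table() -> CriteriaTable:
    """The six loop-interaction criteria of the synthetic active site."""
    entries = [
        Criterion("ala97_hb", "hbond", "A:ALA:97:O", "polar", None, True),
        Criterion("arg98_cb_hydrophobic", "hydrophobic", "A:ARG:98:CB", "nonpolar_carbon", None, True),
        Criterion("arg98_electrostatic", "electrostatic", "A:ARG:98:NH1", "anion", None, True),
        Criterion("gln99_hb", "hbond", "A:GLN:99:NE2", "polar", None, True),
        Criterion("arg105_hb1", "hbond", "A:ARG:105:NH2", "polar", None, True),
        Criterion("arg105_hb2", "hbond", "A:ARG:105:NE", "polar", None, True),
    ]
    return CriteriaTable(entries=entries)


def make_active_site(seed: int = 0) -> tuple[Structure, CriteriaTable]:
    """Build the synthetic receptor fragment and its criteria table.

    Loop-residue analogs (Ala97, Arg98, Gln99, Arg105) and the anchor
    arginine (Arg168) are placed on a spread-out layout with ideal planar
    guanidinium groups.  The seed spins each residue about its outward axis —
    a nuisance rotation that changes coordinates but no planted property.
    """
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    for resnum, (resname, probe) in sorted(_SITE_RESIDUES.items()):
        target, outward = _SITE_LAYOUT[resnum]
        spin = float(rng.uniform(0, 2 * math.pi))
        placed = _place_template(_TEMPLATES[resname], probe, target, _unit(outward), spin)
        atoms.extend(_make_residue_atoms(resname, resnum, placed))
    site = Structure(id=f"synthsite-{seed}", atoms=atoms)
    return site, default_criteria_table()


# ---------------------------------------------------------------------------
# Pose planting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoseSpec:
    """Desired, verifiable outcomes of a planted pose.

    ``arg168_distance`` — carboxyl-carbon to Arg168 CZ distance, Å (None:
    the pose carries no carboxylate at all);
    ``bidentate`` — whether the carboxylate chelates the Arg168 guanidinium
    with twin hydrogen bonds;
    ``criteria`` — labels of loop criteria the pose must satisfy, exactly
    (any criterion not listed must come out unsatisfied).
    """

    arg168_distance: Optional[float] = None
    bidentate: bool = False
    criteria: tuple[str, ...] = ()


# With the carboxylate facing the guanidinium mouth, each planted N···O pair
# measures (CZ–C distance) − 1.252 Å; the twin bond therefore needs
# CZ–C <= 3.5 + 1.252.  With the oxygens flipped away the nearest N···O is
# (CZ–C) − 0.078 Å, so suppressing all hydrogen bonds needs CZ–C >= ~3.7.
_BIDENTATE_MAX_CC = 3.5 + 1.252
_NO_HBOND_MIN_CC = 3.7
_CARBOXYL_HALF_ANGLE = math.radians(62.0)  # half of the O-C-O angle


def _carboxylate_atoms(
    site: Structure,
    cc_distance: float,
    facing: bool,
    resnum: int = 168,
) -> list[tuple[str, np.ndarray]]:
    """Carboxylate fragment at an exact CZ–C distance from the anchor
    arginine, either chelating the guanidinium (``facing``) or turned away."""
    frame = {
        n: next(
            a.coords
            for a in site.atoms
            if a.residue_number == resnum and a.name == n
        )
        for n in ("CZ", "NE", "NH1", "NH2")
    }
    u = _unit((frame["NH1"] + frame["NH2"]) / 2 - frame["CZ"])  # mouth
    v = _unit(frame["NH1"] - frame["NH2"])
    c = frame["CZ"] + cc_distance * u
    sign = -1.0 if facing else 1.0
    cos_a, sin_a = math.cos(_CARBOXYL_HALF_ANGLE), math.sin(_CARBOXYL_HALF_ANGLE)
    o1 = c + 1.25 * (sign * cos_a * u + sin_a * v)
    o2 = c + 1.25 * (sign * cos_a * u - sin_a * v)
    atoms = [("C1", c), ("O1", o1), ("O2", o2)]
    if facing:
        atoms.append(("C2", c + 1.52 * u))  # acid body, away from the mouth
    return atoms


def plant_pose(
    site: Structure,
    criteria: CriteriaTable,
    spec: PoseSpec,
    seed: int = 0,
    cutoffs: GeometricCutoffs = GeometricCutoffs(),
    chain_id: str = "A",
) -> list[Atom]:
    """Place a small carboxylate-bearing scaffold realising ``spec`` exactly.

    The returned pose, when fingerprinted with the given cutoffs, reproduces
    the spec: the Arg168 carboxyl-carbon distance to 0.01 Å, the bidentate
    flag, and exactly the requested satisfied criteria.  Infeasible
    combinations raise :class:`InfeasiblePoseError` naming the conflict.
    The pipeline's own detectors re-check every planted outcome before the
    pose is returned.
    """
    rng = np.random.default_rng(seed)
    unknown = [l for l in spec.criteria if l not in {e.label for e in criteria.entries}]
    if unknown:
        raise InfeasiblePoseError(f"unknown criteria labels: {unknown}")

    placed: list[tuple[str, str, np.ndarray]] = []  # (name, element, coords)
    if spec.bidentate and spec.arg168_distance is None:
        raise InfeasiblePoseError("bidentate requires a carboxylate (set arg168_distance)")
    if spec.arg168_distance is not None:
        d = spec.arg168_distance
        if spec.bidentate and d > _BIDENTATE_MAX_CC:
            raise InfeasiblePoseError(
                f"bidentate twin bond impossible at CZ-C distance {d:.2f} Å "
                f"(needs <= {_BIDENTATE_MAX_CC:.2f})"
            )
        if not spec.bidentate and d < _NO_HBOND_MIN_CC:
            raise InfeasiblePoseError(
                f"suppressing the twin bond impossible at CZ-C distance {d:.2f} Å "
                f"(needs >= {_NO_HBOND_MIN_CC:.2f})"
            )
        for name, coords in _carboxylate_atoms(site, d, facing=spec.bidentate):
            placed.append((name, _element_of(name), coords))

    # one probe atom per requested criterion, pointed away from any sibling
    # criterion atom on the same residue so nothing is satisfied by accident
    receptor_atoms = {}
    for e in criteria.entries:
        _, resname, resnum, atom_name = e.receptor_parts()
        a = site.find_atom(chain_id, resnum, atom_name)
        if a is None:
            raise InfeasiblePoseError(f"criterion {e.label!r}: receptor atom missing")
        receptor_atoms[e.label] = a
    site_center = np.mean([a.coords for a in receptor_atoms.values()], axis=0)
    role_atom = {"polar": "O", "nonpolar_carbon": "C", "anion": "P"}
    serial = 10
    for label in spec.criteria:
        e = next(x for x in criteria.entries if x.label == label)
        target = receptor_atoms[label]
        siblings = [
            receptor_atoms[x.label].coords
            for x in criteria.entries
            if x.label != label
            and np.linalg.norm(receptor_atoms[x.label].coords - target.coords) < 6.0
        ]
        if siblings:
            direction = _unit(target.coords - np.mean(siblings, axis=0))
        else:
            direction = _unit(target.coords - site_center)
        cutoff = e.cutoff if e.cutoff is not None else cutoffs.for_kind(e.kind)
        element = role_atom.get(e.ligand_role)
        if element is None:
            raise InfeasiblePoseError(
                f"criterion {label!r}: cannot plant role {e.ligand_role!r}"
            )
        serial += 1
        placed.append((f"{element}{serial}", element, target.coords + (cutoff - 0.6) * direction))

    # nuisance decoy far from everything
    decoy_dir = _unit(rng.normal(size=3))
    placed.append(("C99", "C", site_center + 40.0 * decoy_dir))

    pose = [
        Atom(
            name=name,
            element=element,
            coords=coords,
            residue_name="LIG",
            residue_number=401,
            chain_id="X",
            is_hetero=True,
        )
        for name, element, coords in placed
    ]
    _verify_pose(site, criteria, spec, pose, cutoffs, chain_id)
    return pose


def _verify_pose(site, criteria, spec, pose, cutoffs, chain_id) -> None:
    fp = fingerprint_pose(site, chain_id, pose, criteria, cutoffs)
    problems = []
    got = {label for label, ok in fp.satisfied.items() if ok}
    if got != set(spec.criteria):
        problems.append(f"criteria satisfied {sorted(got)} != requested {sorted(spec.criteria)}")
    if fp.has_bidentate_arg168 != spec.bidentate:
        problems.append(f"bidentate {fp.has_bidentate_arg168} != requested {spec.bidentate}")
    if spec.arg168_distance is not None:
        _, dist, _ = arg168_distance_filter(pose, site, chain_id)
        if not math.isfinite(dist) or abs(dist - spec.arg168_distance) > 0.01:
            problems.append(
                f"Arg168 CZ-C distance {dist:.3f} != requested {spec.arg168_distance:.3f}"
            )
    if problems:
        raise InfeasiblePoseError("; ".join(problems))


# ---------------------------------------------------------------------------
# Library with a planted stage-failure plan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StageFailurePlan:
    """How many library members fail at each funnel stage (the rest pass).

    ``n_loop_fail`` compounds satisfy exactly one loop criterion: they fail a
    two-interaction (Model 2) run and pass a one-interaction (Model 1) run.
    """

    n: int
    n_lipinski_fail: int
    n_arg168_fail: int
    n_bidentate_fail: int
    n_loop_fail: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("library size must be >= 1")
        total_fail = (
            self.n_lipinski_fail
            + self.n_arg168_fail
            + self.n_bidentate_fail
            + self.n_loop_fail
        )
        if total_fail > self.n:
            raise ValueError("stage-failure counts exceed library size")

    @property
    def n_full_pass(self) -> int:
        return self.n - (
            self.n_lipinski_fail
            + self.n_arg168_fail
            + self.n_bidentate_fail
            + self.n_loop_fail
        )

    @classmethod
    def from_fractions(cls, n: int, fractions: dict[str, float]) -> "StageFailurePlan":
        if sum(fractions.values()) > 1.0 + 1e-9:
            raise ValueError("fractions sum must be <= 1")
        return cls(
            n=n,
            n_lipinski_fail=round(n * fractions.get("lipinski", 0.0)),
            n_arg168_fail=round(n * fractions.get("arg168", 0.0)),
            n_bidentate_fail=round(n * fractions.get("bidentate", 0.0)),
            n_loop_fail=round(n * fractions.get("loop", 0.0)),
        )


#: The 83-compound screening scenario used throughout the tests: a library the
#: size of the rule-of-five-filtered set of pyruvate/oxamate derivatives, with
#: failures planted at every funnel stage.
FUNNEL83_PLAN = StageFailurePlan(
    n=83, n_lipinski_fail=10, n_arg168_fail=20, n_bidentate_fail=30, n_loop_fail=15
)


@dataclass
class FixtureManifest:
    """Ground truth for a generated library: fully determines funnel output."""

    seed: int
    plan: dict
    ligands: dict[str, dict]  # id -> planted outcomes
    expected: dict[str, dict]  # per model: survivor counts + selected ids

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "plan": self.plan,
                "ligands": self.ligands,
                "expected": self.expected,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FixtureManifest":
        d = json.loads(text)
        return cls(seed=d["seed"], plan=d["plan"], ligands=d["ligands"], expected=d["expected"])


# oxamate-family scaffolds; descriptor blocks are planted per the stage plan,
# the SMILES provide realistic connectivity for descriptor recomputation demos
_SCAFFOLDS = (
    "NC(=O)C(=O)O",        # oxamic acid
    "CNC(=O)C(=O)O",       # N-methyl
    "CCNC(=O)C(=O)O",      # N-ethyl
    "CC(C)NC(=O)C(=O)O",   # N-isopropyl
    "CCCNC(=O)C(=O)O",     # N-propyl
    "CC(=O)C(=O)O",        # pyruvic acid
    "OC(=O)C(=O)O",        # oxalic acid
    "OCC(=O)C(=O)O",       # hydroxy-pyruvate
)


def _planted_descriptors(rng: np.random.Generator, fail: bool, which: int) -> dict:
    """A descriptor block that passes the rule of five, or violates exactly
    one chosen rule; passing blocks occasionally sit exactly on a boundary."""
    block = {
        "molecular_weight": float(np.round(rng.uniform(89.0, 420.0), 2)),
        "logp": float(np.round(rng.uniform(-2.0, 4.5), 2)),
        "hbond_donors": int(rng.integers(0, 5)),
        "hbond_acceptors": int(rng.integers(1, 10)),
    }
    if fail:
        rule = which % 4
        if rule == 0:
            block["molecular_weight"] = float(np.round(rng.uniform(501.0, 750.0), 2))
        elif rule == 1:
            block["logp"] = float(np.round(rng.uniform(5.1, 7.5), 2))
        elif rule == 2:
            block["hbond_donors"] = int(rng.integers(6, 9))
        else:
            block["hbond_acceptors"] = int(rng.integers(11, 14))
    elif which % 7 == 0:
        # exercise boundary inclusivity: exactly at a limit is a pass
        boundary = ("molecular_weight", "logp", "hbond_donors", "hbond_acceptors")[which % 4]
        block[boundary] = {"molecular_weight": 500.0, "logp": 5.0,
                           "hbond_donors": 5, "hbond_acceptors": 10}[boundary]
    return block


def make_library(
    n: int = FUNNEL83_PLAN.n,
    plan: Optional[StageFailurePlan] = None,
    seed: int = 0,
    site: Optional[Structure] = None,
    criteria: Optional[CriteriaTable] = None,
) -> tuple[list[LigandRecord], dict[str, list[list[Atom]]], FixtureManifest]:
    """Generate a descriptor-annotated library, one planted pose per ligand,
    and the manifest of expected funnel outcomes.

    Group membership is shuffled by the seeded generator; the manifest records
    the planted truth per ligand plus the expected per-stage survivor counts
    and selected sets for Model 1 and Model 2 runs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if plan is None:
        plan = StageFailurePlan(n, 0, 0, 0, 0)
    if plan.n != n:
        raise ValueError("plan.n must equal n")
    if site is None or criteria is None:
        site, criteria = make_active_site(seed)
    rng = np.random.default_rng(seed)

    groups = (
        ["lipinski_fail"] * plan.n_lipinski_fail
        + ["arg168_fail"] * plan.n_arg168_fail
        + ["bidentate_fail"] * plan.n_bidentate_fail
        + ["loop_fail"] * plan.n_loop_fail
        + ["full_pass"] * plan.n_full_pass
    )
    groups = [groups[i] for i in rng.permutation(n)]

    loop_labels = [e.label for e in criteria.loop_entries()]
    records: list[LigandRecord] = []
    poses: dict[str, list[list[Atom]]] = {}
    ligands_truth: dict[str, dict] = {}
    for i, group in enumerate(groups):
        lig_id = f"SYN{i + 1:04d}"
        descriptors = _planted_descriptors(rng, group == "lipinski_fail", i)
        records.append(
            LigandRecord(
                id=lig_id,
                smiles=_SCAFFOLDS[i % len(_SCAFFOLDS)],
                descriptors=descriptors,
            )
        )
        if group == "arg168_fail":
            spec = PoseSpec(arg168_distance=float(np.round(rng.uniform(4.8, 6.5), 2)),
                            bidentate=False)
        elif group == "bidentate_fail":
            chosen = tuple(
                sorted(rng.choice(loop_labels, size=2, replace=False).tolist())
            )
            spec = PoseSpec(arg168_distance=float(np.round(rng.uniform(3.8, 4.4), 2)),
                            bidentate=False, criteria=chosen)
        elif group == "loop_fail":
            chosen = (str(rng.choice(loop_labels)),)
            spec = PoseSpec(arg168_distance=float(np.round(rng.uniform(2.9, 4.0), 2)),
                            bidentate=True, criteria=chosen)
        else:  # full_pass and lipinski_fail both get a clean passing pose
            k = int(rng.integers(2, min(4, len(loop_labels)) + 1))
            chosen = tuple(sorted(rng.choice(loop_labels, size=k, replace=False).tolist()))
            spec = PoseSpec(arg168_distance=float(np.round(rng.uniform(2.9, 4.0), 2)),
                            bidentate=True, criteria=chosen)
        pose_seed = int(rng.integers(0, 2**31 - 1))
        poses[lig_id] = [plant_pose(site, criteria, spec, seed=pose_seed)]
        ligands_truth[lig_id] = {
            "group": group,
            "lipinski_pass": group != "lipinski_fail",
            "arg168_distance": spec.arg168_distance,
            "arg168_pass": (
                spec.arg168_distance is not None and spec.arg168_distance <= 4.5
            ),
            "bidentate": spec.bidentate,
            "loop_criteria": list(spec.criteria),
            "loop_count": len(spec.criteria),
        }

    expected = {}
    for model_id, min_loop in ((1, 1), (2, 2)):
        lip = [i for i in ligands_truth if ligands_truth[i]["lipinski_pass"]]
        arg = [i for i in lip if ligands_truth[i]["arg168_pass"]]
        bid = [i for i in arg if ligands_truth[i]["bidentate"]]
        sel = [i for i in bid if ligands_truth[i]["loop_count"] >= min_loop]
        expected[f"model{model_id}"] = {
            "survivor_counts": {
                "intake": n,
                "lipinski": len(lip),
                "pose_present": len(lip),
                "arg168_filter": len(arg),
                "bidentate": len(bid),
                "loop_criterion": len(sel),
                "selected": len(sel),
            },
            "selected_ids": sorted(sel),
        }

    manifest = FixtureManifest(
        seed=seed,
        plan={
            "n": plan.n,
            "n_lipinski_fail": plan.n_lipinski_fail,
            "n_arg168_fail": plan.n_arg168_fail,
            "n_bidentate_fail": plan.n_bidentate_fail,
            "n_loop_fail": plan.n_loop_fail,
        },
        ligands=ligands_truth,
        expected=expected,
    )
    return records, poses, manifest


# ---------------------------------------------------------------------------
# Loop-conformer ensembles
# ---------------------------------------------------------------------------

#: Mutual loop-Cα RMSD planted between the two default open conformers,
#: matching the apo-form subunit pair variability (Å).
OPEN_LOOP_PAIR_RMSD = 2.09

_LOOP_RANGE = (96, 111)
_CHAIN_RANGE = (85, 125)


def make_loop_ensemble(
    displacement_plan: Sequence,
    seed: int = 0,
    loop_range: tuple[int, int] = _LOOP_RANGE,
) -> tuple[
    Structure,
    list[Structure],
    dict,
    AtomSelector,
    AtomSelector,
]:
    """Cα-trace conformer ensemble with analytically known loop RMSDs.

    The reference chain is a seeded 3.8 Å-step random walk over residues
    85–125.  Each plan entry produces one conformer sharing the non-loop atoms
    exactly, with loop Cα displaced by: a scalar ``d`` (uniform shift of the
    whole loop along +x → RMSD d), a 3-vector (uniform shift along it → RMSD
    |v|; mutual RMSD between two such conformers |v_i − v_j|), or a length-16
    array of per-atom magnitudes applied along seeded random directions
    (→ RMSD sqrt(mean d_i²); mutual values not closed-form, reported as None).

    Returns (reference, conformers, expected, fit_selector, report_selector)
    where ``expected`` holds ``rmsd_to_reference`` per conformer and the
    ``pairwise`` closed-form values, and the selectors encode the intended
    fit (non-loop Cα, exact identity fit) and report (loop Cα) atom sets.
    """
    rng = np.random.default_rng(seed)
    lo, hi = loop_range
    resnums = list(range(_CHAIN_RANGE[0], _CHAIN_RANGE[1] + 1))
    steps = rng.normal(size=(len(resnums) - 1, 3))
    steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])

    def chain_atoms(xyz: np.ndarray) -> list[Atom]:
        return [
            Atom(name="CA", element="C", coords=xyz[k], residue_name="GLY",
                 residue_number=resnums[k], chain_id="A")
            for k in range(len(resnums))
        ]

    reference = Structure(id="ref", atoms=chain_atoms(coords))
    loop_idx = [k for k, r in enumerate(resnums) if lo <= r <= hi]

    conformers: list[Structure] = []
    shift_vectors: list[Optional[np.ndarray]] = []
    expected_to_ref: list[float] = []
    for c, entry in enumerate(displacement_plan):
        xyz = coords.copy()
        if np.isscalar(entry):
            v = np.array([float(entry), 0.0, 0.0])
            xyz[loop_idx] += v
            shift_vectors.append(v)
            expected_to_ref.append(abs(float(entry)))
        else:
            arr = np.asarray(entry, dtype=float)
            if arr.shape == (3,):
                xyz[loop_idx] += arr
                shift_vectors.append(arr)
                expected_to_ref.append(float(np.linalg.norm(arr)))
            elif arr.shape == (len(loop_idx),):
                dirs = rng.normal(size=(len(loop_idx), 3))
                dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
                xyz[loop_idx] += arr[:, None] * dirs
                shift_vectors.append(None)
                expected_to_ref.append(float(np.sqrt(np.mean(arr**2))))
            else:
                raise ValueError(
                    f"plan entry {c}: expected scalar, 3-vector, or "
                    f"{len(loop_idx)} per-atom magnitudes"
                )
        conformers.append(Structure(id=f"conf{c + 1}", atoms=chain_atoms(xyz)))

    n = len(conformers)
    pairwise: list[list[Optional[float]]] = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            vi, vj = shift_vectors[i], shift_vectors[j]
            pairwise[i][j] = (
                float(np.linalg.norm(vi - vj)) if vi is not None and vj is not None else None
            )
    expected = {"rmsd_to_reference": expected_to_ref, "pairwise": pairwise}
    fit_selector = AtomSelector(atom_names=frozenset({"CA"}),
                                residue_range=(_CHAIN_RANGE[0], lo - 1))
    report_selector = AtomSelector(atom_names=frozenset({"CA"}), residue_range=loop_range)
    return reference, conformers, expected, fit_selector, report_selector


def make_open_loop_pair(seed: int = 0):
    """The default open-state scenario: two conformers displaced ±x so their
    mutual loop RMSD equals :data:`OPEN_LOOP_PAIR_RMSD` (each half that from
    the reference)."""
    half = OPEN_LOOP_PAIR_RMSD / 2.0
    return make_loop_ensemble([(half, 0.0, 0.0), (-half, 0.0, 0.0)], seed=seed)


# ---------------------------------------------------------------------------
# Reference bound complexes (closed-state contact geometry)
# ---------------------------------------------------------------------------

#: Labelled loop-contact distances of the oxamate/NADH closed-state complex.
OXAMATE_COMPLEX_CONTACTS = {
    "Ala97:O~NAI:O3'": 2.88,
    "Arg98:CB~NAI:C2'": 3.71,
    "Arg98:CB~NAI:C3'": 3.56,
    "Arg98:NH1~NAI:P": 4.0,
    "Arg105:NH2~OXM:O1": 2.86,
    "Arg105:NE~OXM:O3": 2.93,
}

#: Labelled loop-contact distances of the 88N inhibitor closed-state complex.
INHIBITOR_88N_COMPLEX_CONTACTS = {
    "Arg98:CB~88N:C21": 4.38,
    "Arg98:CB~88N:C27": 4.45,
    "Gln99:NE2~88N:Ocarboxyl(min)": 2.72,
    "Arg105:NH2~88N:O1A": 3.14,
    "Arg105:NE~88N:O2A": 3.04,
}


def _named_spec(label: str, resname: str, resnum: int, atom: str,
                lig_resname: str, lig_atom: str) -> DistanceSpec:
    return DistanceSpec(
        label=label,
        receptor_selector=AtomSelector(residue_names=frozenset({resname}),
                                       residue_range=(resnum, resnum),
                                       atom_names=frozenset({atom})),
        ligand_selector=AtomSelector(residue_names=frozenset({lig_resname}),
                                     atom_names=frozenset({lig_atom})),
        aggregation="named-atom",
    )


def make_reference_complex(
    kind: str = "oxamate", seed: int = 0
) -> tuple[Structure, list[DistanceSpec], dict[str, float]]:
    """Build a closed-state bound complex whose labelled contact distances
    equal the tabulated closed-state values exactly.

    ``kind='oxamate'`` — the substrate-analog/cofactor complex: oxamate
    chelated by the Arg168 guanidinium (twin bond), hydrogen-bonded to
    Arg105, with cofactor-fragment atoms (nicotinamide-ribose O3'/C2'/C3' and
    a pyrophosphate P) contacting Ala97 and Arg98.

    ``kind='88N'`` — the two-carboxylate inhibitor complex: carboxylate
    oxygens contacting Arg105 and Gln99, plus two non-polar carbons against
    the Arg98 Cβ.

    Returns ``(structure, table, expected)`` where measuring ``table`` on
    chain A reproduces ``expected`` (verified at generation time to 0.005 Å).
    """
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    table: list[DistanceSpec] = []

    if kind == "oxamate":
        expected = dict(OXAMATE_COMPLEX_CONTACTS)
        # Arg168 at the template pose: guanidinium in the xy-plane, mouth +x
        arg168 = {n: c.copy() for n, c in _ARG_TEMPLATE.items()}
        atoms += _make_residue_atoms("ARG", 168, arg168)
        # oxamate chelating the guanidinium: N-O twin bonds at 2.90 Å
        d_cc = 2.90 + 1.2519
        cz = arg168["CZ"]
        u, v = np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
        c1 = cz + d_cc * u
        cos_a, sin_a = math.cos(_CARBOXYL_HALF_ANGLE), math.sin(_CARBOXYL_HALF_ANGLE)
        o1 = c1 + 1.25 * (-cos_a * u + sin_a * v)
        o2 = c1 + 1.25 * (-cos_a * u - sin_a * v)
        c2 = c1 + 1.53 * u
        o3 = c2 + 1.22 * np.array([0.5, 0.866, 0.0])
        n1 = c2 + 1.33 * np.array([0.5, -0.866, 0.0])
        oxm = {"C1": c1, "O1": o1, "O2": o2, "C2": c2, "O3": o3, "N1": n1}
        atoms += _make_residue_atoms("OXM", 301, oxm, hetero=True)

        # Arg105: guanidinium two-anchor placement — NH2 exactly 2.86 from O1,
        # NE exactly 2.93 from O3, chelation geometry above the ligand plane
        p = o1 + 2.86 * np.array([0.0, 1.0, 0.0])
        sep = float(np.linalg.norm(_GUANIDINIUM["NH2"] - _GUANIDINIUM["NE"]))
        q = _sphere_sphere_point(o3, 2.93, p, sep, prefer=p + np.array([0.0, 0.0, 3.0]))
        avoid = [a.coords for a in atoms]
        guanidinium = _place_two_anchor(
            _GUANIDINIUM, "NH2", "NE", p, q, avoid=avoid
        )
        arm_dir = _unit(guanidinium["CZ"] - np.mean([o1, o3], axis=0))
        arg105 = dict(guanidinium)
        for k, name in enumerate(("CD", "CG", "CB", "CA"), start=1):
            arg105[name] = guanidinium["NE"] + 1.5 * k * arm_dir
        atoms += _make_residue_atoms("ARG", 105, arg105)

        # cofactor fragment well away from the substrate site
        offset = np.array([0.0, -10.0, 0.0])
        nai = {
            "C3'": offset + np.array([0.0, 0.0, 0.0]),
            "C2'": offset + np.array([1.53, 0.0, 0.0]),
            "O3'": offset + np.array([-0.715, 1.238, 0.0]),
            "P": offset + np.array([4.0, 2.0, 2.0]),
        }
        atoms += _make_residue_atoms("NAI", 302, nai, hetero=True)

        # Ala97: backbone O exactly 2.88 from O3'
        o97 = nai["O3'"] + 2.88 * _unit(np.array([-1.0, 0.3, 0.2]))
        ala97 = _place_template(_ALA_TEMPLATE, "O", o97, _unit(np.array([-1.0, 0.3, 0.2])))
        atoms += _make_residue_atoms("ALA", 97, ala97)

        # Arg98: CB on the exact intersection of the C2'/C3' spheres; the
        # guanidinium is placed separately with NH1 exactly 4.0 from P, the
        # connecting side-chain carbons interpolated
        cb = _sphere_sphere_point(
            nai["C2'"], 3.71, nai["C3'"], 3.56,
            prefer=nai["C3'"] + np.array([0.0, -5.0, -2.0]),
        )
        nh1_dir = _unit(cb + np.array([0.0, -2.0, -1.0]) - nai["P"])
        nh1 = nai["P"] + 4.0 * nh1_dir
        gua98 = _place_template(
            _GUANIDINIUM, "NH1", nh1, _unit(nh1 - nai["P"]),
        )
        arg98 = dict(gua98)
        gap = cb - gua98["NE"]
        for k, name in enumerate(("CD", "CG"), start=1):
            arg98[name] = gua98["NE"] + gap * k / 3.0
        arg98["CB"] = cb
        arg98["CA"] = cb + 1.53 * _unit(cb - nai["C3'"])
        atoms += _make_residue_atoms("ARG", 98, arg98)

        table = [
            _named_spec("Ala97:O~NAI:O3'", "ALA", 97, "O", "NAI", "O3'"),
            _named_spec("Arg98:CB~NAI:C2'", "ARG", 98, "CB", "NAI", "C2'"),
            _named_spec("Arg98:CB~NAI:C3'", "ARG", 98, "CB", "NAI", "C3'"),
            _named_spec("Arg98:NH1~NAI:P", "ARG", 98, "NH1", "NAI", "P"),
            _named_spec("Arg105:NH2~OXM:O1", "ARG", 105, "NH2", "OXM", "O1"),
            _named_spec("Arg105:NE~OXM:O3", "ARG", 105, "NE", "OXM", "O3"),
        ]
        structure = Structure(id=f"synth-oxm-{seed}", atoms=atoms)

    elif kind == "88N":
        expected = dict(INHIBITOR_88N_COMPLEX_CONTACTS)
        arg105 = {n: c.copy() for n, c in _ARG_TEMPLATE.items()}
        atoms += _make_residue_atoms("ARG", 105, arg105)
        nh2, ne = arg105["NH2"], arg105["NE"]
        # first carboxylate: one oxygen exactly 3.14 from NH2
        o1a = nh2 + 3.14 * _unit(np.array([0.5, -0.866, 0.0]))
        ca_c = o1a + 1.25 * _unit(np.array([0.3, -1.0, 0.1]))
        o1b = ca_c + 1.25 * _unit(
            _axis_rotation(np.array([0.0, 0.0, 1.0]), math.radians(126.0))
            @ (o1a - ca_c)
        )
        # second carboxylate: one oxygen exactly 3.04 from NE
        o2a = ne + 3.04 * _unit(np.array([-0.866, -0.5, 0.0]))
        cb_c = o2a + 1.25 * _unit(np.array([0.2, -1.0, -0.1]))
        o2b = cb_c + 1.25 * _unit(
            _axis_rotation(np.array([0.0, 0.0, 1.0]), math.radians(-126.0))
            @ (o2a - cb_c)
        )
        # two non-polar carbons exactly 4.38/4.45 from the Arg98 CB (below)
        lig = {"O1A": o1a, "C1A": ca_c, "O1B": o1b,
               "O2A": o2a, "C1B": cb_c, "O2B": o2b}
        atoms_88n_center = np.mean([o1a, o2a], axis=0)

        # Gln99: NE2 exactly 2.72 from the second carboxylate oxygen
        ne2_dir = _unit(np.array([-0.7, -0.7, 0.3]))
        ne2 = o2a + 2.72 * ne2_dir
        gln99 = _place_template(_GLN_TEMPLATE, "NE2", ne2, ne2_dir)
        atoms += _make_residue_atoms("GLN", 99, gln99)

        # Arg98 at a spread position; the hydrophobic probes hang off its CB
        arg98 = _place_template(
            _ARG_TEMPLATE, "CB", np.array([7.0, 2.0, 3.0]),
            _unit(np.array([1.0, 0.5, 0.5])), spin=float(rng.uniform(0, 2 * math.pi)),
        )
        atoms += _make_residue_atoms("ARG", 98, arg98)
        cb98 = arg98["CB"]
        lig["C21"] = cb98 + 4.38 * _unit(np.array([0.9, 0.3, 0.3]))
        lig["C27"] = cb98 + 4.45 * _unit(np.array([0.8, 0.55, 0.25]))
        atoms += _make_residue_atoms("88N", 303, lig, hetero=True)

        table = [
            _named_spec("Arg98:CB~88N:C21", "ARG", 98, "CB", "88N", "C21"),
            _named_spec("Arg98:CB~88N:C27", "ARG", 98, "CB", "88N", "C27"),
            DistanceSpec(
                label="Gln99:NE2~88N:Ocarboxyl(min)",
                receptor_selector=AtomSelector(
                    residue_names=frozenset({"GLN"}), residue_range=(99, 99),
                    atom_names=frozenset({"NE2"}),
                ),
                ligand_selector=AtomSelector(residue_names=frozenset({"88N"})),
                aggregation="min",
                ligand_role="carboxylate_oxygen",
            ),
            _named_spec("Arg105:NH2~88N:O1A", "ARG", 105, "NH2", "88N", "O1A"),
            _named_spec("Arg105:NE~88N:O2A", "ARG", 105, "NE", "88N", "O2A"),
        ]
        structure = Structure(id=f"synth-88n-{seed}", atoms=atoms)
    else:
        raise ValueError(f"unknown reference complex kind {kind!r}")

    _verify_reference_complex(structure, table, expected, kind)
    return structure, table, expected


def _verify_reference_complex(structure, table, expected, kind) -> None:
    from .geometry import measure_contact_table

    frame = measure_contact_table(structure, "A", table)
    measured = dict(zip(frame["label"], frame["distance_A"]))
    for label, value in expected.items():
        if abs(measured[label] - value) > 0.005:
            raise AssertionError(
                f"{kind} reference complex: {label} measured {measured[label]:.3f}, "
                f"planted {value:.3f}"
            )
    if kind == "oxamate":
        arg168 = [a for a in structure.atoms if a.residue_number == 168]
        oxm = [a for a in structure.atoms if a.residue_name == "OXM"]
        if not detect_bidentate_arginine(arg168, oxm).is_bidentate:
            raise AssertionError("oxamate reference complex lost the twin bond")
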