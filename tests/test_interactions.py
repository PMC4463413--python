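"""Contact detectors, bidentate recognition, and pose fingerprints."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pose_triage import synthetic_data as synth
from pose_triage.geometry import RigidTransform
from pose_triage.interactions import (
    CriteriaTable,
    GeometricCutoffs,
    detect_bidentate_arginine,
    detect_electrostatic,
    detect_hbonds,
    detect_hydrophobic,
    find_carboxylate_groups,
    fingerprint_pose,
)
from pose_triage.structure_io import Structure

from conftest import make_atom


def brute_force_pairs(receptor, ligand, cutoff, rec_ok, lig_ok):
    """Independent all-pairs scan used as the detector oracle."""
    hits = set()
    for r in receptor:
        if not rec_ok(r):
            continue
        for l in ligand:
            if not lig_ok(l):
                continue
            if float(np.linalg.norm(r.coords - l.coords)) <= cutoff:
                hits.add((id(r), id(l)))
    return hits


def guanidinium_atoms():
    return [
        make_atom("CZ", "C", (0.0, 0.0, 0.0), resname="ARG", resnum=168, hetero=False),
        make_atom("NE", "N", (-1.33, 0.0, 0.0), resname="ARG", resnum=168, hetero=False),
        make_atom("NH1", "N", (0.665, 1.152, 0.0), resname="ARG", resnum=168, hetero=False),
        make_atom("NH2", "N", (0.665, -1.152, 0.0), resname="ARG", resnum=168, hetero=False),
    ]


def carboxylate(c_xyz, o1_xyz, o2_xyz):
    return [
        make_atom("C1", "C", c_xyz),
        make_atom("O1", "O", o1_xyz),
        make_atom("O2", "O", o2_xyz),
    ]


class TestDetectors:
    def test_hbond_inside_and_outside_cutoff(self):
        receptor = [make_atom("N", "N", (0, 0, 0), resname="GLY", resnum=10, hetero=False)]
        near = [make_atom("O1", "O", (2.8, 0, 0))]
        far = [make_atom("O1", "O", (4.0, 0, 0))]
        assert len(detect_hbonds(receptor, near)) == 1
        assert detect_hbonds(receptor, far) == []

    def test_hydrophobic_inside_and_outside_cutoff(self):
        receptor = [make_atom("CB", "C", (0, 0, 0), resname="ALA", resnum=10, hetero=False)]
        assert len(detect_hydrophobic(receptor, [make_atom("C5", "C", (4.2, 0, 0))])) == 1
        assert detect_hydrophobic(receptor, [make_atom("C5", "C", (5.0, 0, 0))]) == []

    def test_polar_carbons_are_not_hydrophobic(self):
        receptor = [make_atom("CB", "C", (0, 0, 0), resname="ALA", resnum=10, hetero=False)]
        # ligand carbon 1.25 Å from an oxygen -> polar, excluded
        ligand = [
            make_atom("C1", "C", (4.0, 0, 0)),
            make_atom("O1", "O", (4.0, 1.25, 0)),
        ]
        assert detect_hydrophobic(receptor, ligand) == []

    def test_electrostatic_guanidinium_to_phosphorus(self):
        receptor = guanidinium_atoms()
        near = [make_atom("P", "P", (0.665, 1.152 + 3.9, 0.0))]
        far = [make_atom("P", "P", (0.665, 1.152 + 6.0, 0.0))]
        assert len(detect_electrostatic(receptor, near)) == 1
        assert detect_electrostatic(receptor, far) == []

    def test_detectors_match_brute_force_scan_on_planted_poses(self, site_and_criteria):
        site, criteria = site_and_criteria
        pose = synth.plant_pose(
            site,
            criteria,
            synth.PoseSpec(
                arg168_distance=3.2,
                bidentate=True,
                criteria=("arg105_hb1", "arg105_hb2", "gln99_hb", "ala97_hb"),
            ),
            seed=3,
        )
        cutoffs = GeometricCutoffs()
        receptor = [a for a in site.atoms if a.element != "H"]
        got = {
            (id(c.receptor_atom), id(c.ligand_atom))
            for c in detect_hbonds(receptor, pose, cutoffs)
        }
        expected = brute_force_pairs(
            receptor,
            pose,
            cutoffs.hbond_max,
            rec_ok=lambda a: a.element in ("N", "O"),
            lig_ok=lambda a: a.element in ("N", "O"),
        )
        assert got == expected

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.floats(min_value=0.0, max_value=2.0))
    def test_enlarging_cutoffs_never_loses_contacts(self, delta):
        site, criteria = synth.make_active_site(seed=11)
        pose = synth.plant_pose(
            site,
            criteria,
            synth.PoseSpec(arg168_distance=3.5, bidentate=True, criteria=("arg105_hb1",)),
            seed=4,
        )
        base = GeometricCutoffs()
        wider = GeometricCutoffs(
            hbond_max=base.hbond_max + delta,
            hydrophobic_max=base.hydrophobic_max + delta,
            electrostatic_max=base.electrostatic_max + delta,
        )
        receptor = site.atoms
        assert len(detect_hbonds(receptor, pose, wider)) >= len(
            detect_hbonds(receptor, pose, base)
        )
        assert len(detect_hydrophobic(receptor, pose, wider)) >= len(
            detect_hydrophobic(receptor, pose, base)
        )
        assert len(detect_electrostatic(receptor, pose, wider)) >= len(
            detect_electrostatic(receptor, pose, base)
        )


class TestCarboxylateRecognition:
    def test_connectivity_based_group(self):
        atoms = carboxylate((0, 0, 0), (0.587, 1.104, 0), (0.587, -1.104, 0))
        ((c, oxygens),) = find_carboxylate_groups(atoms)
        assert c.name == "C1"
        assert {o.name for o in oxygens} == {"O1", "O2"}

    def test_ester_like_oxygen_excluded(self):
        # the second oxygen bridges to another carbon -> not carboxylate-like
        atoms = carboxylate((0, 0, 0), (0.587, 1.104, 0), (0.587, -1.104, 0))
        atoms.append(make_atom("C2", "C", (1.087, -2.3, 0)))  # bonded to O2 only
        assert find_carboxylate_groups(atoms) == []


class TestBidentate:
    def test_twin_bond_detected(self):
        ligand = carboxylate((1.15, 3.39, 0), (0.0, 2.9, 0.0), (2.3, 2.9, 0.0))
        result = detect_bidentate_arginine(guanidinium_atoms(), ligand)
        assert result.is_bidentate
        assert len(result.contacts) == 2

    def test_single_contact_is_not_twin(self):
        ligand = carboxylate((1.15, 3.91, 0), (1.15, 2.66, 0.0), (1.15, 5.16, 0.0))
        # O1 is within reach of both NH1 and NH2; O2 is far from every nitrogen
        result = detect_bidentate_arginine(guanidinium_atoms(), ligand)
        assert not result.is_bidentate
        assert result.reason == "geometry"

    def test_no_carboxylate_distinguishable(self):
        ligand = [make_atom("O1", "O", (0.665, 2.9, 0.0))]
        result = detect_bidentate_arginine(guanidinium_atoms(), ligand)
        assert not result.is_bidentate
        assert result.reason == "no carboxylate"

    def test_missing_guanidinium_is_an_error(self):
        with pytest.raises(ValueError, match="guanidinium"):
            detect_bidentate_arginine(
                [make_atom("CB", "C", (0, 0, 0), resname="ARG", resnum=168, hetero=False)],
                carboxylate((0, 3, 0), (1, 3, 0), (-1, 3, 0)),
            )

    def test_reference_oxamate_complex_is_bidentate(self, oxamate_complex):
        structure, _, _ = oxamate_complex
        arg168 = [a for a in structure.atoms if a.residue_number == 168]
        oxm = [a for a in structure.atoms if a.residue_name == "OXM"]
        assert detect_bidentate_arginine(arg168, oxm).is_bidentate


class TestFingerprint:
    @pytest.mark.parametrize(
        "labels",
        [
            (),
            ("arg105_hb1", "arg105_hb2"),
            ("arg105_hb1", "arg105_hb2", "gln99_hb", "arg98_cb_hydrophobic"),
            ("arg98_electrostatic",),
        ],
    )
    def test_planted_criteria_round_trip_exactly(self, site_and_criteria, labels):
        site, criteria = site_and_criteria
        spec = synth.PoseSpec(arg168_distance=3.0, bidentate=True, criteria=labels)
        pose = synth.plant_pose(site, criteria, spec, seed=7)
        fp = fingerprint_pose(site, "A", pose, criteria)
        assert {l for l, ok in fp.satisfied.items() if ok} == set(labels)
        assert fp.loop_interaction_count == len(labels)
        assert fp.has_bidentate_arg168

    def test_count_is_per_criterion_not_per_atom_pair(self, site_and_criteria):
        site, criteria = site_and_criteria
        pose = synth.plant_pose(
            site, criteria,
            synth.PoseSpec(arg168_distance=3.0, bidentate=True, criteria=("arg105_hb1",)),
            seed=8,
        )
        probe = next(a for a in pose if a.name.startswith("O") and a.name not in ("O1", "O2"))
        duplicated = pose + [
            make_atom("O98", "O", probe.coords + np.array([0.3, 0.0, 0.0]))
        ]
        fp = fingerprint_pose(site, "A", duplicated, criteria)
        assert fp.loop_interaction_count == 1

    def test_distant_pose_has_zero_loop_interactions(self, site_and_criteria):
        site, criteria = site_and_criteria
        pose = [make_atom("O1", "O", (200.0, 200.0, 200.0))]
        fp = fingerprint_pose(site, "A", pose, criteria)
        assert fp.loop_interaction_count == 0
        assert not fp.has_bidentate_arg168

    def test_unresolvable_criterion_excluded_from_count(self, site_and_criteria):
        site, criteria = site_and_criteria
        from pose_triage.interactions import Criterion

        extended = CriteriaTable(
            entries=criteria.entries
            + [Criterion("ghost", "hbond", "A:SER:100:OG", "polar", None, True)]
        )
        pose = synth.plant_pose(
            site, criteria,
            synth.PoseSpec(arg168_distance=3.0, bidentate=True, criteria=("gln99_hb",)),
            seed=9,
        )
        fp = fingerprint_pose(site, "A", pose, extended)
        assert "ghost" in fp.unresolvable
        assert fp.loop_interaction_count == 1

    def test_invariant_under_common_rigid_motion(self, site_and_criteria):
        from scipy.spatial.transform import Rotation

        site, criteria = site_and_criteria
        pose = synth.plant_pose(
            site, criteria,
            synth.PoseSpec(arg168_distance=3.4, bidentate=True,
                           criteria=("arg105_hb1", "gln99_hb")),
            seed=10,
        )
        rng = np.random.default_rng(0)
        T = RigidTransform(
            Rotation.from_rotvec(rng.uniform(-np.pi, np.pi, 3)).as_matrix(),
            rng.uniform(-20, 20, 3),
        )
        moved_site = Structure(
            id=site.id, atoms=[a.moved_to(T.apply(a.coords)) for a in site.atoms]
        )
        moved_pose = [a.moved_to(T.apply(a.coords)) for a in pose]
        fp0 = fingerprint_pose(site, "A", pose, criteria)
        fp1 = fingerprint_pose(moved_site, "A", moved_pose, criteria)
        assert fp0.satisfied == fp1.satisfied
        assert fp0.has_bidentate_arg168 == fp1.has_bidentate_arg168
        assert fp0.loop_interaction_count == fp1.loop_interaction_count


class TestCriteriaTable:
    def test_loop_member_flag_must_match_residue_number(self):
        from pose_triage.interactions import Criterion

        with pytest.raises(ValueError, match="loop_member"):
            CriteriaTable(
                entries=[Criterion("bad", "hbond", "A:ARG:168:NH1", "polar", None, True)]
            )

    def test_config_round_trip(self, site_and_criteria):
        from pose_triage.interactions import format_criteria_table, parse_criteria_table

        _, criteria = site_and_criteria
        back = parse_criteria_table(format_criteria_table(criteria))
        assert back.entries == criteria.entries
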