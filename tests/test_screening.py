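"""Rule-of-five filtering, descriptor computation, and the screening funnel."""

import json

import numpy as np
import pytest

from pose_triage import synthetic_data as synth
from pose_triage.screening import (
    DescriptorBlock,
    ScreenConfig,
    arg168_distance_filter,
    compute_descriptors,
    lipinski_pass,
    run_funnel,
    write_report,
)
from pose_triage.structure_io import LigandRecord

from conftest import make_atom


class TestLipinski:
    def test_boundary_values_pass(self):
        ok, violations = lipinski_pass(DescriptorBlock(500.0, 5.0, 5, 10))
        assert ok and violations == []

    def test_single_violation_named(self):
        ok, violations = lipinski_pass(DescriptorBlock(501.0, 0.0, 0, 0))
        assert not ok and violations == ["molecular_weight"]

    def test_multiple_violations_listed(self):
        ok, violations = lipinski_pass(DescriptorBlock(600.0, 6.0, 7, 12))
        assert not ok
        assert set(violations) == {
            "molecular_weight",
            "logp",
            "hbond_donors",
            "hbond_acceptors",
        }

    def test_oxamate_like_compound_passes(self):
        descriptors = compute_descriptors(LigandRecord(id="oxamic", smiles="NC(=O)C(=O)O"))
        ok, violations = lipinski_pass(descriptors)
        assert ok and violations == []


class TestDescriptors:
    def test_methane_has_no_donors_or_acceptors(self):
        d = compute_descriptors(LigandRecord(id="methane", smiles="C"))
        assert d.hbond_donors == 0 and d.hbond_acceptors == 0

    def test_water_counts(self):
        d = compute_descriptors(LigandRecord(id="water", smiles="O"))
        assert d.hbond_donors == 1 and d.hbond_acceptors == 1

    def test_ethanol_molecular_weight(self):
        d = compute_descriptors(LigandRecord(id="ethanol", smiles="CCO"))
        assert d.molecular_weight == pytest.approx(46.07, abs=0.01)

    def test_unparsable_molecule_errors(self):
        with pytest.raises(ValueError):
            compute_descriptors(LigandRecord(id="junk", smiles="((("))


class TestArg168Filter:
    def test_boundary_inclusive(self, site_and_criteria):
        site, criteria = site_and_criteria
        near = synth.plant_pose(
            site, criteria, synth.PoseSpec(arg168_distance=4.4, bidentate=True), seed=0
        )
        ok, dist, _ = arg168_distance_filter(near, site, "A")
        assert ok and dist == pytest.approx(4.4, abs=0.01)
        far = synth.plant_pose(
            site, criteria, synth.PoseSpec(arg168_distance=4.6, bidentate=True), seed=0
        )
        ok, dist, _ = arg168_distance_filter(far, site, "A")
        assert not ok and dist == pytest.approx(4.6, abs=0.01)

    def test_min_over_multiple_carboxyl_carbons(self, site_and_criteria):
        site, _ = site_and_criteria
        cz = next(
            a for a in site.atoms if a.residue_number == 168 and a.name == "CZ"
        )
        def group(dist, tag):
            c = cz.coords + np.array([dist, 0.0, 0.0])
            return [
                make_atom(f"C{tag}", "C", c),
                make_atom(f"O{tag}A", "O", c + [0.587, 1.104, 0]),
                make_atom(f"O{tag}B", "O", c + [0.587, -1.104, 0]),
            ]
        pose = group(6.0, "1") + group(3.0, "2")
        ok, dist, _ = arg168_distance_filter(pose, site, "A")
        assert ok and dist == pytest.approx(3.0, abs=1e-9)

    def test_no_carboxylate_fails_with_reason(self, site_and_criteria):
        site, _ = site_and_criteria
        ok, dist, reason = arg168_distance_filter(
            [make_atom("C1", "C", (0, 0, 0))], site, "A"
        )
        assert not ok and reason == "no carboxyl carbon"

    def test_missing_anchor_arginine_is_config_error(self, site_and_criteria):
        site, _ = site_and_criteria
        with pytest.raises(ValueError, match="CZ"):
            arg168_distance_filter([make_atom("C1", "C", (0, 0, 0))], site, "B")


def _single_ligand_setup(site, criteria, spec, seed=1):
    record = LigandRecord(
        id="L1",
        smiles="NC(=O)C(=O)O",
        descriptors={
            "molecular_weight": 89.05,
            "logp": -1.1,
            "hbond_donors": 2,
            "hbond_acceptors": 4,
        },
    )
    pose = synth.plant_pose(site, criteria, spec, seed=seed)
    return [record], {"L1": [pose]}


class TestFunnel:
    def test_single_passing_ligand_selected_with_full_audit(self, site_and_criteria):
        site, criteria = site_and_criteria
        library, poses = _single_ligand_setup(
            site,
            criteria,
            synth.PoseSpec(arg168_distance=3.0, bidentate=True,
                           criteria=("arg105_hb1", "arg105_hb2")),
        )
        cfg = ScreenConfig(receptor=site, chain_id="A", criteria=criteria, model_id=2)
        report = run_funnel(library, poses, cfg)
        (outcome,) = report.outcomes
        assert outcome.selected
        assert outcome.lipinski and outcome.pose_present and outcome.arg168_pass
        assert outcome.bidentate and outcome.loop_count == 2

    def test_one_loop_interaction_splits_the_models(self, site_and_criteria):
        site, criteria = site_and_criteria
        library, poses = _single_ligand_setup(
            site,
            criteria,
            synth.PoseSpec(arg168_distance=3.0, bidentate=True, criteria=("gln99_hb",)),
        )
        for model_id, expected in ((1, True), (2, False)):
            cfg = ScreenConfig(receptor=site, chain_id="A", criteria=criteria,
                               model_id=model_id)
            report = run_funnel(library, poses, cfg)
            assert report.outcomes[0].selected is expected

    def test_best_pose_reported_by_arg168_distance(self, site_and_criteria):
        site, criteria = site_and_criteria
        library, _ = _single_ligand_setup(site, criteria, synth.PoseSpec())
        pose_far = synth.plant_pose(
            site, criteria,
            synth.PoseSpec(arg168_distance=4.2, bidentate=True, criteria=("gln99_hb",)),
            seed=2,
        )
        pose_near = synth.plant_pose(
            site, criteria,
            synth.PoseSpec(arg168_distance=3.1, bidentate=True, criteria=("gln99_hb",)),
            seed=3,
        )
        cfg = ScreenConfig(receptor=site, chain_id="A", criteria=criteria, model_id=1)
        report = run_funnel(library, {"L1": [pose_far, pose_near]}, cfg)
        (outcome,) = report.outcomes
        assert outcome.best_pose_index == 1
        assert outcome.arg168_distance == pytest.approx(3.1, abs=0.01)

    def test_unknown_pose_id_and_empty_library_error(self, site_and_criteria):
        site, criteria = site_and_criteria
        library, poses = _single_ligand_setup(site, criteria, synth.PoseSpec(
            arg168_distance=3.0, bidentate=True))
        cfg = ScreenConfig(receptor=site, chain_id="A", criteria=criteria)
        with pytest.raises(ValueError, match="unknown ligand"):
            run_funnel(library, {"L1": poses["L1"], "ghost": poses["L1"]}, cfg)
        with pytest.raises(ValueError, match="empty library"):
            run_funnel([], poses, cfg)

    def test_funnel_is_monotone_and_conserves_ligands(self, site_and_criteria):
        site, criteria = site_and_criteria
        records, poses, _ = synth.make_library(
            n=30, plan=synth.StageFailurePlan(30, 4, 6, 8, 6), seed=13,
            site=site, criteria=criteria,
        )
        cfg = ScreenConfig(receptor=site, chain_id="A", criteria=criteria, model_id=2)
        report = run_funnel(records, poses, cfg)
        c = report.survivor_counts
        order = ["intake", "lipinski", "pose_present", "arg168_filter",
                 "bidentate", "loop_criterion"]
        values = [c[k] for k in order]
        assert values == sorted(values, reverse=True)
        assert set(report.selected_ids) <= {r.id for r in records}
        assert len(report.outcomes) == len(records)

    def test_relaxing_thresholds_never_shrinks_selection(self, site_and_criteria):
        site, criteria = site_and_criteria
        records, poses, _ = synth.make_library(
            n=25, plan=synth.StageFailurePlan(25, 3, 5, 6, 5), seed=17,
            site=site, criteria=criteria,
        )
        strict = ScreenConfig(receptor=site, chain_id="A", criteria=criteria,
                              model_id=2)
        relaxed = ScreenConfig(receptor=site, chain_id="A", criteria=criteria,
                               model_id=2, arg168_carbon_max=6.0,
                               min_loop_interactions=1)
        sel_strict = set(run_funnel(records, poses, strict).selected_ids)
        sel_relaxed = set(run_funnel(records, poses, relaxed).selected_ids)
        assert sel_strict <= sel_relaxed


class TestReport:
    def test_csv_and_summary_consistent(self, site_and_criteria, tmp_path):
        import pandas as pd

        site, criteria = site_and_criteria
        records, poses, _ = synth.make_library(
            n=20, plan=synth.StageFailurePlan(20, 3, 4, 5, 3), seed=19,
            site=site, criteria=criteria,
        )
        cfg = ScreenConfig(receptor=site, chain_id="A", criteria=criteria, model_id=2)
        report = run_funnel(records, poses, cfg)
        csv_path, json_path = write_report(report, tmp_path / "out")
        frame = pd.read_csv(csv_path)
        summary = json.loads(json_path.read_text())
        assert len(frame) == 20
        assert int(frame["selected"].fillna(False).sum()) == summary["selected_count"]
        assert summary["survivor_counts"] == report.survivor_counts
        recount = int((frame["lipinski"] == True).sum())  # noqa: E712
        assert recount == summary["survivor_counts"]["lipinski"]

    def test_reports_are_byte_identical_across_runs(self, site_and_criteria, tmp_path):
        site, criteria = site_and_criteria
        records, poses, _ = synth.make_library(
            n=12, plan=synth.StageFailurePlan(12, 2, 2, 2, 2), seed=23,
            site=site, criteria=criteria,
        )
        cfg = ScreenConfig(receptor=site, chain_id="A", criteria=criteria)
        paths = []
        for run in ("a", "b"):
            report = run_funnel(records, poses, cfg)
            paths.append(write_report(report, tmp_path / run))
        assert paths[0][0].read_bytes() == paths[1][0].read_bytes()
        assert paths[0][1].read_bytes() == paths[1][1].read_bytes()
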