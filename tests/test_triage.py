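"""Pose triage: anchor distances, pocket criterion, scaffold RMSD, selection."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import malkit as mk
from malkit.errors import TemplateError, UsageError

from conftest import brute_force_scaffold_rmsd


def _make_result(pose_id, rmsd, in_pocket, score=None):
    dists = mk.DistanceSet(1.0, 1.0, 1.0, 1.0)
    n = 4 if in_pocket else 0
    return mk.TriageResult(
        pose_id=pose_id,
        distances=dists,
        n_below_cutoff=n,
        in_pocket=in_pocket,
        scaffold_rmsd=rmsd,
        mapping_used={},
        docking_score=score,
    )


class TestMeasureDistances:
    def test_reference_geometry(self, pocket):
        _, reference, anchors, template = pocket
        d = mk.measure_distances(reference, template, anchors)
        assert d.as_tuple() == pytest.approx((4.16, 3.08, 2.75, 2.2), abs=1e-9)
        assert d.carboxyl_choice == 0

    def test_min_over_oxygens_never_exceeds_either(self, pocket):
        _, reference, anchors, template = pocket
        d = mk.measure_distances(reference, template, anchors)
        group = template.carboxyl_groups[d.carboxyl_choice]
        for anchor, value in [
            (anchors.q329_amide_n, d.d_q329_o),
            (anchors.h194_eps_n, d.d_h194_o),
            (anchors.mg, d.d_mg_o),
        ]:
            for oxy in (group.oxygen1, group.oxygen2):
                sep = np.linalg.norm(reference.atom(oxy).position - anchor.position)
                assert value <= sep + 1e-12

    def test_equidistant_oxygens_tie(self, pocket):
        # the fixture Mg sits on the carboxylate bisector: both oxygens at 2.2
        _, reference, anchors, template = pocket
        d = mk.measure_distances(reference, template, anchors)
        for oxy in ("O41", "O42"):
            assert np.linalg.norm(
                reference.atom(oxy).position - anchors.mg.position
            ) == pytest.approx(d.d_mg_o, abs=1e-9)

    def test_unresolvable_label(self, pocket):
        _, reference, anchors, _ = pocket
        broken = mk.get_template("beta-glutamate")  # C5 carboxyl absent here
        with pytest.raises(TemplateError):
            mk.measure_distances(reference, broken, anchors)


class TestPocketCriterion:
    @pytest.mark.parametrize(
        "distances,expected_n,expected_in",
        [
            ((4.16, 3.08, 2.75, 2.2), 3, True),  # 4.16 is not below 4
            ((10, 10, 10, 3), 1, False),
            ((3.9, 3.9, 3.9, 3.9), 4, True),
            ((4.0, 4.0, 4.0, 4.0), 0, False),  # strict inequality at the cutoff
        ],
    )
    def test_strict_count(self, pocket, distances, expected_n, expected_in):
        anchors = pocket[2]
        d = mk.DistanceSet(*distances)
        n, inside = mk.pose_in_pocket(d, anchors)
        assert (n, inside) == (expected_n, expected_in)

    def test_raising_cutoff_is_monotone(self, pocket):
        _, reference, anchors, template = pocket
        d = mk.measure_distances(reference, template, anchors)
        counts = [
            mk.pose_in_pocket(d, replace(anchors, cutoff=c))[0]
            for c in (1.0, 2.5, 3.0, 4.0, 4.5, 10.0)
        ]
        assert counts == sorted(counts)

    def test_far_translation_never_in_pocket(self, pocket):
        _, reference, anchors, template = pocket
        offset = anchors.cutoff + max(anchors.reference_distances)
        rng = np.random.default_rng(7)
        for _ in range(20):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            far = reference.translated(direction * offset * 1.01)
            d = mk.measure_distances(far, template, anchors)
            assert not mk.pose_in_pocket(d, anchors)[1]


class TestScaffoldRmsd:
    def test_self_is_zero_with_identity_mapping(self, pocket):
        _, reference, _, template = pocket
        rmsd, mapping = mk.scaffold_rmsd(reference, reference, template)
        assert rmsd == 0.0
        assert mapping == {
            "pose_carboxyl": 0,
            "reference_carboxyl": 0,
            "oxygen_swap": False,
        }

    def test_rigid_translation_is_exact(self, pocket):
        _, reference, _, template = pocket
        shifted = reference.translated((3.0, 0.0, 0.0))
        rmsd, _ = mk.scaffold_rmsd(shifted, reference, template)
        assert rmsd == pytest.approx(3.0, abs=1e-12)

    @pytest.mark.parametrize("name", mk.list_templates())
    def test_matches_brute_force_oracle_all_templates(self, name):
        template = mk.get_template(name)
        rng = np.random.default_rng(sum(map(ord, name)))
        labels = sorted(
            {
                lbl
                for i in range(len(template.carboxyl_groups))
                for lbl in template.scaffold_labels(i)
            }
            | set(template.amino_nitrogens)
        )
        def rand_pose(pid):
            return mk.LigandPose(
                pose_id=pid,
                ligand_name=name,
                atoms=[
                    mk.Atom(lbl, lbl[0], "LIG", 1, "X", rng.normal(size=3) * 4)
                    for lbl in labels
                ],
            )
        reference = rand_pose(0)
        for pid in range(1, 11):
            pose = rand_pose(pid)
            rmsd, _ = mk.scaffold_rmsd(pose, reference, template)
            assert rmsd == pytest.approx(
                brute_force_scaffold_rmsd(pose, reference, template), abs=1e-9
            )

    def test_symmetry_never_worse_than_fixed_mapping(self, pocket):
        # dicarboxylic ligand: the symmetry minimum is <= the identity mapping
        _, reference, _, template = pocket
        rng = np.random.default_rng(11)
        for _ in range(20):
            pose = reference.translated(rng.normal(size=3))
            rmsd, _ = mk.scaffold_rmsd(pose, reference, template)
            labels = template.scaffold_labels(0)
            p = np.array([pose.atom(n).position for n in labels])
            r = np.array([reference.atom(n).position for n in labels])
            fixed = np.sqrt(np.mean(np.sum((p - r) ** 2, axis=1)))
            assert rmsd <= fixed + 1e-12


class TestSelection:
    def test_lowest_in_pocket_rmsd_wins(self):
        results = [
            _make_result(1, 2.1, True),
            _make_result(2, 1.5, True),
            _make_result(3, 1.2, False),
        ]
        assert mk.select_pose(results).pose_id == 2

    def test_single_pose(self):
        only = _make_result(1, 0.4, True)
        assert mk.select_pose([only]) is only

    def test_no_selection_outcome(self):
        results = [_make_result(1, 1.0, False), _make_result(2, 2.0, False)]
        assert mk.select_pose(results) is None

    def test_tie_broken_by_score_then_id(self):
        results = [
            _make_result(3, 1.0, True, score=-5.0),
            _make_result(1, 1.0, True, score=-7.0),
            _make_result(2, 1.0, True, score=-7.0),
        ]
        assert mk.select_pose(results).pose_id == 1

    def test_empty_is_usage_error(self):
        with pytest.raises(UsageError):
            mk.select_pose([])


class TestPercentAndReport:
    def test_percent_known_labels(self, pocket):
        _, reference, anchors, template = pocket
        pose_set = mk.generate_poses(
            reference,
            mk.PoseSimConfig(n_in_pocket=40, n_decoys=60, seed=5),
            template,
            anchors,
        )
        results = []
        for pose in pose_set.poses:
            d = mk.measure_distances(pose, template, anchors)
            n, inside = mk.pose_in_pocket(d, anchors)
            results.append(_make_result(pose.pose_id, 0.0, inside))
        assert mk.percent_in_pocket(results) == pytest.approx(0.40)

    def test_percent_invariant_to_ordering(self):
        results = [_make_result(i, 1.0, i % 3 == 0) for i in range(1, 10)]
        assert mk.percent_in_pocket(results) == mk.percent_in_pocket(results[::-1])

    def test_report_consistent_with_components(self, pocket):
        receptor, reference, anchors, template = pocket
        pose_set = mk.generate_poses(
            reference,
            mk.PoseSimConfig(n_in_pocket=5, n_decoys=5, seed=2),
            template,
            anchors,
        )
        report = mk.triage_ligand(
            receptor, pose_set.poses, template, anchors, reference
        )
        for pose, result in zip(pose_set.poses, report.results):
            d = mk.measure_distances(pose, template, anchors)
            assert result.distances == d
            assert result.scaffold_rmsd == pytest.approx(
                mk.scaffold_rmsd(pose, reference, template)[0]
            )
        assert report.selected is not None and report.selected.in_pocket
        assert report.percent_in_pocket == pytest.approx(0.5)
        frame = report.to_frame()
        assert len(frame) == 10 and "scaffold_rmsd" in frame.columns

    def test_reference_as_sole_pose(self, pocket):
        receptor, reference, anchors, template = pocket
        report = mk.triage_ligand(receptor, [reference], template, anchors, reference)
        assert report.selected.pose_id == reference.pose_id
        assert report.selected.scaffold_rmsd == 0.0
        assert report.percent_in_pocket == 1.0

    def test_empty_pose_list(self, pocket):
        receptor, reference, anchors, template = pocket
        with pytest.raises(UsageError):
            mk.triage_ligand(receptor, [], template, anchors, reference)


_ANCHORS = mk.anchors_from_structure(mk.make_pocket_fixture()[0])


@settings(derandomize=True, max_examples=100)
@given(
    distances=st.tuples(*(st.floats(0.0, 12.0) for _ in range(4))),
    lo=st.floats(0.5, 8.0),
    hi=st.floats(0.5, 8.0),
)
def test_pocket_count_monotone_in_cutoff(distances, lo, hi):
    """Raising the distance cutoff can never lower the below-cutoff count."""
    lo, hi = min(lo, hi), max(lo, hi)
    d = mk.DistanceSet(*distances)
    n_lo = mk.pose_in_pocket(d, replace(_ANCHORS, cutoff=lo))[0]
    n_hi = mk.pose_in_pocket(d, replace(_ANCHORS, cutoff=hi))[0]
    assert n_lo <= n_hi
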