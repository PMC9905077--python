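"""Pre/post differencing, insertion depth, Eshraghi grading, trauma reports."""

import numpy as np
import pytest

from cochlect.core import LabelVolume
from cochlect import coords, trauma
from cochlect.phantom import LABELS, Lesion, generate_phantom, insert_electrode
from conftest import fast_spec


class TestEshraghiGrade:
    @pytest.mark.parametrize("descriptors,expected", [
        (set(), 0),
        ({"BM elevation"}, 1),
        ({"BM rupture"}, 2),
        ({"electrode in scala vestibuli"}, 3),
        ({"OSL fracture"}, 4),
        ({"modiolus fracture"}, 4),
        ({"SL/stria tear"}, 4),
        ({"BM elevation", "OSL fracture"}, 4),  # ordinal: maximum wins
        ({"none", "BM rupture"}, 2),
    ])
    def test_scale(self, descriptors, expected):
        assert trauma.eshraghi_grade(descriptors) == expected

    def test_unknown_descriptor_rejected(self):
        with pytest.raises(ValueError, match="unknown trauma descriptor"):
            trauma.eshraghi_grade({"stapes subluxation"})


class TestDiffStructures:
    def test_identical_volumes_give_empty_masks(self, small_phantom):
        masks = trauma.diff_structures(small_phantom.labels, small_phantom.labels)
        assert all(not m.any() for m in masks.values())

    def test_grid_mismatch_rejected(self, small_phantom):
        other = LabelVolume(
            small_phantom.labels.data[:-2].copy(),
            small_phantom.labels.voxel_size_um,
            dict(small_phantom.labels.names),
        )
        with pytest.raises(ValueError, match="grids differ"):
            trauma.diff_structures(small_phantom.labels, other)

    def test_clean_insertion_leaves_walls_untouched(self, small_phantom):
        post = insert_electrode(small_phantom, 380.0)
        masks = trauma.diff_structures(small_phantom.labels, post.labels)
        assert all(not m.any() for m in masks.values())

    def test_removed_lesion_recovered_exactly(self, small_phantom):
        post = insert_electrode(
            small_phantom, 380.0, [Lesion("osl", "fracture", 100.0, 200.0)]
        )
        masks = trauma.diff_structures(small_phantom.labels, post.labels)
        assert int(masks["osl"].sum()) == int(post.lesion_table.iloc[0].affected_voxels)
        assert not masks["sl"].any()


class TestTraumatizedFraction:
    def test_empty_mask_is_zero_percent(self, small_phantom):
        empty = np.zeros(small_phantom.labels.shape, bool)
        assert trauma.traumatized_fraction(small_phantom.labels, empty, "osl") == 0.0

    def test_full_removal_is_hundred_percent(self, small_phantom):
        full = small_phantom.labels.data == LABELS["osl"]
        assert trauma.traumatized_fraction(small_phantom.labels, full, "osl") == 100.0

    def test_fraction_matches_generator_bookkeeping(self, small_phantom):
        post = insert_electrode(
            small_phantom, 380.0, [Lesion("sl", "tear", 150.0, 220.0)]
        )
        masks = trauma.diff_structures(small_phantom.labels, post.labels)
        pct = trauma.traumatized_fraction(small_phantom.labels, masks["sl"], "sl")
        assert pct == pytest.approx(post.lesion_table.iloc[0].affected_pct, abs=0.1)

    def test_empty_structure_rejected(self, small_phantom):
        empty = np.zeros(small_phantom.labels.shape, bool)
        lab = small_phantom.labels.copy()
        lab.names["ghost"] = 99
        with pytest.raises(ValueError, match="no voxels"):
            trauma.traumatized_fraction(lab, empty, "ghost")


class TestInsertionDepth:
    def test_recovers_generated_depth(self, desk_phantom, desk_frame, post_phantom):
        ref = coords.build_reference(post_phantom.labels, desk_frame)
        depth = trauma.insertion_depth(
            post_phantom.labels.data == LABELS["electrode"],
            desk_frame,
            post_phantom.labels.voxel_size_um,
            ref,
        )
        assert depth == pytest.approx(380.0, abs=3.0)

    def test_short_insertion_stays_proximal(self, small_phantom):
        post = insert_electrode(small_phantom, 15.0)
        frame = coords.fit_frame(post.labels)
        ref = coords.build_reference(post.labels, frame)
        depth = trauma.insertion_depth(
            post.labels.data == LABELS["electrode"], frame, 70.0, ref
        )
        assert depth <= 20.0

    def test_empty_electrode_rejected(self, desk_frame, desk_reference):
        with pytest.raises(ValueError, match="empty"):
            trauma.insertion_depth(np.zeros((4, 4, 4), bool), desk_frame, 35.0, desk_reference)

    def test_depth_invariant_under_rotation(self, small_phantom):
        post = insert_electrode(small_phantom, 300.0)
        d = []
        for lab in (post.labels, LabelVolume(np.ascontiguousarray(np.rot90(post.labels.data, axes=(1, 2))), 70.0, dict(post.labels.names))):
            frame = coords.fit_frame(lab)
            ref = coords.build_reference(lab, frame)
            d.append(trauma.insertion_depth(lab.data == LABELS["electrode"], frame, 70.0, ref))
        assert d[1] == pytest.approx(d[0], abs=3.0)


class TestTraumaReport:
    def test_round_trip_matches_generator_ground_truth(self, desk_phantom, desk_frame, post_phantom):
        report = trauma.build_trauma_report(
            desk_phantom.labels,
            post_phantom.labels,
            desk_frame,
            thickness_lookup_um={"bm": desk_phantom.spec.bm_thickness},
        )
        expected_grades = {"osl": 4, "sl": 4, "bm": 1}
        for _, gt in post_phantom.lesion_table.iterrows():
            row = report[report.structure == gt.structure].iloc[0]
            assert row.trauma_volume_mm3 == pytest.approx(gt.affected_mm3, rel=0.02)
            assert row.percent_of_pre == pytest.approx(gt.affected_pct, abs=0.2)
            assert row.theta_start_deg == pytest.approx(gt.theta_start, abs=3.0)
            assert row.theta_end_deg == pytest.approx(gt.theta_end, abs=3.0)
            assert row.eshraghi_grade == expected_grades[gt.structure]
        assert report.attrs["composite_grade"] == 4
        assert report.attrs["insertion_depth_deg"] == pytest.approx(380.0, abs=3.0)

    def test_untraumatized_insertion_reports_grade_zero(self, small_phantom):
        post = insert_electrode(small_phantom, 380.0)
        frame = coords.fit_frame(post.labels)
        report = trauma.build_trauma_report(small_phantom.labels, post.labels, frame)
        assert report.attrs["composite_grade"] == 0
        assert set(report.structure) == {"overall"}

    def test_adding_a_lesion_never_lowers_fraction_or_grade(self, small_phantom):
        one = insert_electrode(small_phantom, 380.0, [Lesion("osl", "fracture", 100.0, 160.0)])
        two = insert_electrode(
            small_phantom,
            380.0,
            [Lesion("osl", "fracture", 100.0, 160.0), Lesion("osl", "fracture", 200.0, 240.0)],
        )
        frame = coords.fit_frame(small_phantom.labels)
        r1 = trauma.build_trauma_report(small_phantom.labels, one.labels, frame)
        r2 = trauma.build_trauma_report(small_phantom.labels, two.labels, frame)
        p1 = r1[r1.structure == "osl"].percent_of_pre.iloc[0]
        p2 = r2[r2.structure == "osl"].percent_of_pre.iloc[0]
        assert p2 >= p1
        assert r2.attrs["composite_grade"] >= r1.attrs["composite_grade"]

    def test_translocation_grades_three(self, small_phantom):
        post = insert_electrode(
            small_phantom,
            380.0,
            [Lesion("scala_vestibuli", "scala-vestibuli translocation", 250.0, 330.0)],
        )
        frame = coords.fit_frame(post.labels)
        report = trauma.build_trauma_report(small_phantom.labels, post.labels, frame)
        assert report.attrs["composite_grade"] >= 3
        descriptors = set(report.descriptor.dropna())
        assert any("scala vestibuli" in d for d in descriptors)

    def test_subresolution_membrane_flagged_unreliable(self):
        # 25 µm basilar membrane segmented at 18.9 µm: rasterizes (one voxel)
        # but is thinner than two voxels, so its volume is not trustworthy
        spec = fast_spec(
            grid_shape=(96, 144, 144),
            voxel_size=18.9,
            turns=1.2,
            basal_radius=750.0,
            pitch=820.0,
            cross_section_scale=0.35,
            bm_thickness=25.0,
            rm_thickness=20.0,
            rwm_thickness=60.0,
            osl_thickness=60.0,
            scala_media_radius=70.0,
            rc_radius=160.0,
            capsule_thickness=100.0,
            ssl_end=200.0,
            rwa_end=40.0,
            rc_start=5.0,
            rc_end=300.0,
        )
        ph = generate_phantom(spec)
        post = insert_electrode(ph, 300.0, [Lesion("bm", "tear", 120.0, 200.0)], electrode_radius_um=30.0)
        frame = coords.fit_frame(post.labels)
        report = trauma.build_trauma_report(
            ph.labels, post.labels, frame,
            thickness_lookup_um={"bm": spec.bm_thickness, "rwm": spec.rwm_thickness},
        )
        bm = report[report.structure == "bm"].iloc[0]
        assert bm.volume_unreliable
        assert bm.eshraghi_grade == 2
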