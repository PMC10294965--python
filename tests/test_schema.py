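"""Channel schema, taxonomy, impairment categories, and recording I/O."""

import numpy as np
import pytest

from primood.schema import (
    PrimitiveClass, MOTION_BASED, Recording, Segment, SubjectMeta,
    build_channel_schema, impairment_category, validate_recording,
    read_csv, read_hdf5, write_csv, write_hdf5,
)
from .conftest import make_recording


class TestTaxonomy:
    def test_five_classes_three_motion_based(self):
        assert len(list(PrimitiveClass)) == 5
        assert sum(p.is_motion_based for p in PrimitiveClass) == 3
        assert MOTION_BASED == {PrimitiveClass.REACH, PrimitiveClass.TRANSPORT,
                                PrimitiveClass.REPOSITION}


class TestChannelSchema:
    def test_canonical_counts(self):
        sch = build_channel_schema("right")
        kinds = [c.kind for c in sch.entries]
        assert len(sch.entries) == 76
        assert kinds.count("acceleration") == 27
        assert kinds.count("orientation") == 27
        assert kinds.count("joint_angle") == 22

    def test_trunk_tagged_channels(self):
        # 3 back sensors x (3 accel + 3 orient) + 6 thorax/lumbar angles
        sch = build_channel_schema("right")
        assert len(sch.indices(side_tag="trunk")) == 24
        assert len(sch.indices(side_tag="moving_ue")) == 26
        assert len(sch.indices(side_tag="contralateral_ue")) == 26

    def test_mirror_symmetry(self):
        left = build_channel_schema("left")
        right = build_channel_schema("right")
        assert sorted((c.kind, c.axis) for c in left.entries) == \
            sorted((c.kind, c.axis) for c in right.entries)
        # tags mirror: left's moving channels are right's contralateral ones
        for cl, cr in zip(left.entries, right.entries):
            if cl.side_tag == "moving_ue" and "left" in cl.body_location:
                assert cr.side_tag == "contralateral_ue"
            assert (cl.side_tag == "trunk") == (cr.side_tag == "trunk")

    def test_deterministic(self):
        a = build_channel_schema("right")
        b = build_channel_schema("right")
        assert a.entries == b.entries

    def test_invalid_side(self):
        with pytest.raises(ValueError):
            build_channel_schema("up")


class TestImpairmentCategory:
    @pytest.mark.parametrize("score,expected", [
        (0, "severe"), (25, "severe"), (26, "moderate"), (52, "moderate"),
        (53, "mild"), (65, "mild"), (66, "none"),
    ])
    def test_bands(self, score, expected):
        assert impairment_category(score) == expected

    def test_monotone_step_function(self):
        order = {"severe": 0, "moderate": 1, "mild": 2, "none": 3}
        cats = [order[impairment_category(s)] for s in range(67)]
        assert cats == sorted(cats)

    @pytest.mark.parametrize("score", [-1, 67])
    def test_domain_error(self, score):
        with pytest.raises(ValueError):
            impairment_category(score)


class TestSubjectMeta:
    def test_healthy_must_be_category_none(self):
        with pytest.raises(ValueError):
            SubjectMeta("a", "healthy", 66, "mild")

    def test_impaired_score_ceiling(self):
        with pytest.raises(ValueError):
            SubjectMeta("a", "impaired", 66, "mild")


class TestValidateRecording:
    def test_well_formed(self):
        rec = make_recording([(PrimitiveClass.REACH, 60), (PrimitiveClass.IDLE, 40)])
        assert validate_recording(rec, build_channel_schema("right")) == []

    def test_overlapping_segments_named(self):
        rec = make_recording([(PrimitiveClass.REACH, 60), (PrimitiveClass.IDLE, 40)])
        rec.segments[1] = Segment(50, 100, PrimitiveClass.IDLE)
        v = validate_recording(rec, build_channel_schema("right"))
        assert any("overlap" in msg and "[0,60)" in msg and "[50,100)" in msg
                   for msg in v)

    def test_wrong_channel_count(self):
        rec = make_recording([(PrimitiveClass.IDLE, 50)], n_channels=75)
        v = validate_recording(rec, build_channel_schema("right"))
        assert any("75" in msg for msg in v)

    def test_gap_and_tail_detected(self):
        rec = make_recording([(PrimitiveClass.REACH, 60), (PrimitiveClass.IDLE, 40)])
        rec.segments[1] = Segment(70, 90, PrimitiveClass.IDLE)
        v = validate_recording(rec, build_channel_schema("right"))
        assert any("gap" in m for m in v)
        assert any("ends at" in m for m in v)


class TestSerialization:
    def test_csv_round_trip(self, tmp_path):
        rec = make_recording([(PrimitiveClass.REACH, 60), (PrimitiveClass.IDLE, 40)],
                             seed=3)
        sch = build_channel_schema("right")
        write_csv(rec, sch, tmp_path / "d.csv", tmp_path / "l.csv")
        back = read_csv(tmp_path / "d.csv", tmp_path / "l.csv")
        np.testing.assert_allclose(back.data, rec.data, atol=1e-9)
        assert back.segments == rec.segments

    def test_hdf5_round_trip(self, tmp_path):
        rec = make_recording([(PrimitiveClass.TRANSPORT, 80), (PrimitiveClass.IDLE, 20)],
                             subject="s1", trial="R2", seed=4)
        write_hdf5(rec, tmp_path / "r.h5")
        back = read_hdf5(tmp_path / "r.h5")
        np.testing.assert_array_equal(back.data, rec.data)
        assert back.segments == rec.segments
        assert (back.subject_id, back.trial_id, back.side) == ("s1", "R2", "right")
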