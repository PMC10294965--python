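"""Synthetic generator: impairment model, kinematics, task grammar."""

import numpy as np
import pytest
from scipy import stats

from primood.schema import PrimitiveClass, SubjectMeta, build_channel_schema, validate_recording
from primood.synth import (
    ImpairmentModel, SynthConfig, fma_like_score, generate_subject,
    primitive_kinematics, simulate_dataset, write_dataset,
)


class TestImpairmentModel:
    def test_theta_zero_is_identity(self):
        m = ImpairmentModel.from_theta(0.0)
        assert (m.amplitude_attenuation, m.slowing_factor,
                m.tremor_amplitude, m.trunk_compensation_gain) == (0.0, 1.0, 0.0, 0.0)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ImpairmentModel.from_theta(1.5)


class TestFmaLikeScore:
    @pytest.mark.parametrize("theta,score", [(1.0, 0), (0.0, 65), (0.2, 52)])
    def test_mapping(self, theta, score):
        assert fma_like_score(theta) == score

    def test_monotone_decreasing(self):
        scores = [fma_like_score(t) for t in np.linspace(0, 1, 30)]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fma_like_score(-0.1)


class TestPrimitiveKinematics:
    def test_idle_is_quiet_and_below_stabilization(self):
        sch = build_channel_schema("right")
        idx = sch.indices(side_tag="moving_ue", kind="acceleration")
        rng = np.random.default_rng(0)
        idle = primitive_kinematics(PrimitiveClass.IDLE, 0.8, rng, noise_sd=0.05)
        stab = primitive_kinematics(PrimitiveClass.STABILIZATION, 0.8, rng, noise_sd=0.05)
        assert np.all(np.abs(idle[:, idx].mean(axis=0)) < 0.05)
        assert idle[:, idx].var() < stab[:, idx].var()

    def test_impairment_attenuates_and_dilates(self):
        sch = build_channel_schema("right")
        idx = sch.indices(side_tag="moving_ue", kind="acceleration")
        healthy = primitive_kinematics(PrimitiveClass.REACH, 0.8,
                                       np.random.default_rng(5))
        imp = ImpairmentModel.from_theta(0.8)
        impaired = primitive_kinematics(PrimitiveClass.REACH,
                                        0.8 * imp.slowing_factor,
                                        np.random.default_rng(5), imp)
        assert impaired.shape[0] > healthy.shape[0]
        # peak of deterministic motion component clearly smaller (tremor is
        # band-limited; the min-jerk peak still drops with attenuation)
        assert np.abs(impaired[:, idx]).max() < np.abs(healthy[:, idx]).max()

    def test_healthy_reach_trunk_angles_quiet(self):
        sch = build_channel_schema("right")
        idx = sch.indices(side_tag="trunk", kind="joint_angle")
        block = primitive_kinematics(PrimitiveClass.REACH, 0.8,
                                     np.random.default_rng(2))
        excursion = block[:, idx].max(axis=0) - block[:, idx].min(axis=0)
        assert np.all(excursion < 1.0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            primitive_kinematics(PrimitiveClass.REACH, 0.0, np.random.default_rng(0))


class TestGenerateSubject:
    def test_healthy_subject_has_ten_recordings(self, tiny_cohort):
        _, metas, recs, _ = tiny_cohort
        healthy = [m for m in metas if m.group == "healthy"]
        for m in healthy:
            assert len(recs[m.subject_id]) == 10
            assert {r.side for r in recs[m.subject_id]} == {"left", "right"}

    def test_impaired_subject_has_five_single_side(self, tiny_cohort):
        _, metas, recs, _ = tiny_cohort
        for m in metas:
            if m.group == "impaired":
                assert len(recs[m.subject_id]) == 5
                assert len({r.side for r in recs[m.subject_id]}) == 1

    def test_segments_tile_and_validate(self, tiny_cohort):
        _, metas, recs, _ = tiny_cohort
        for m in metas[:2]:
            for rec in recs[m.subject_id][:2]:
                assert validate_recording(rec, build_channel_schema(rec.side)) == []

    def test_motion_durations_within_slowed_range(self):
        cfg = SynthConfig(n_healthy=1, n_impaired=1, thetas=(0.6,), seed=5)
        meta = SubjectMeta("s", "impaired", fma_like_score(0.6), "moderate")
        slowing = ImpairmentModel.from_theta(0.6).slowing_factor
        for rec in generate_subject(cfg, meta, 0.6):
            for seg in rec.segments:
                if seg.label.is_motion_based:
                    dur = seg.n_frames / rec.rate_hz
                    assert 0.5 * slowing - 0.02 <= dur <= 1.0 * slowing + 0.02

    def test_reproducible(self):
        cfg = SynthConfig(n_healthy=1, n_impaired=0, thetas=(), seed=9)
        meta = SubjectMeta("h", "healthy")
        a = generate_subject(cfg, meta, 0.0)
        b = generate_subject(cfg, meta, 0.0)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.data, rb.data)
            assert ra.segments == rb.segments

    def test_inconsistent_meta_theta(self):
        cfg = SynthConfig(n_healthy=1, n_impaired=0, thetas=(), seed=9)
        with pytest.raises(ValueError):
            generate_subject(cfg, SubjectMeta("h", "healthy"), 0.5)


class TestDistributionProperties:
    def test_theta_zero_kinematics_are_bit_identical_to_healthy(self):
        """theta=0 impairment is the exact identity on the generator."""
        imp0 = ImpairmentModel.from_theta(0.0)
        for prim in (PrimitiveClass.REACH, PrimitiveClass.IDLE):
            a = primitive_kinematics(prim, 0.7, np.random.default_rng(8))
            b = primitive_kinematics(prim, 0.7, np.random.default_rng(8), imp0)
            np.testing.assert_array_equal(a, b)

    def test_theta_zero_matches_healthy_distribution(self):
        """Two independent theta=0 streams agree within Monte-Carlo error.

        The slow sway makes frames within a block strongly dependent, so
        the Kolmogorov-Smirnov statistic is computed on per-block means
        (effectively independent units), 400 blocks per stream.
        """
        def block_means(seed):
            rng = np.random.default_rng(seed)
            return np.stack([
                primitive_kinematics(PrimitiveClass.REACH, 0.7, rng,
                                     ImpairmentModel.from_theta(0.0)).mean(axis=0)
                for _ in range(400)])
        a, b = block_means(1), block_means(2)
        ks = [stats.ks_2samp(a[:, c], b[:, c]).statistic for c in range(0, 76, 7)]
        assert max(ks) < 0.1

    def test_monotone_distortion_in_theta(self):
        """Time-aligned L2 distance to the theta=0 block grows with theta."""
        base = primitive_kinematics(PrimitiveClass.REACH, 0.7,
                                    np.random.default_rng(5))
        t_base = np.linspace(0, 1, base.shape[0])
        dists = []
        for theta in (0.0, 0.25, 0.5, 0.75, 1.0):
            imp = ImpairmentModel.from_theta(theta)
            blk = primitive_kinematics(PrimitiveClass.REACH,
                                       0.7 * imp.slowing_factor,
                                       np.random.default_rng(5), imp)
            t_blk = np.linspace(0, 1, blk.shape[0])
            aligned = np.stack([np.interp(t_base, t_blk, blk[:, c])
                                for c in range(76)], axis=1)
            dists.append(float(np.linalg.norm(aligned - base)))
        assert dists[0] == 0.0
        assert all(a <= b + 1e-9 for a, b in zip(dists, dists[1:]))


class TestSimulateDataset:
    def test_counts_and_manifest(self, tmp_path):
        cfg = SynthConfig(n_healthy=2, n_impaired=2, thetas=(0.2, 0.8), seed=3,
                          trials_per_side=2)
        manifest = write_dataset(cfg, tmp_path)
        import pandas as pd
        df = pd.read_csv(manifest)
        assert len(df) == 4
        assert set(df.columns) >= {"subject_id", "group", "theta",
                                   "impairment_score", "category", "side"}
        h5s = list(tmp_path.glob("*/*.h5"))
        assert len(h5s) == 2 * 4 + 2 * 2   # healthy both sides, impaired one

    def test_theta_validation(self):
        with pytest.raises(ValueError):
            SynthConfig(n_impaired=1, thetas=(1.2,))
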