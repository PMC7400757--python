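"""Synthetic cohorts: determinism, envelope calibration, planted contrast."""

import numpy as np
import pytest

from eloreta_npv import (
    CohortConfig, apply_average_reference, band_power_timecourse,
    generate_cohort, generate_subject, npv_map, segment_recording,
)
from eloreta_npv.synthetic_cohort import (
    _lognormal_envelope, default_effect_voxels, occipital_voxel,
)


def beta_npv_at_planted(rec, filt, voxels):
    rec = apply_average_reference(rec)
    series = band_power_timecourse(filt, segment_recording(rec), fs=rec.fs)
    nm = npv_map(series)
    return nm.npv[list(voxels), 3].mean()


class TestConfig:
    def test_effect_voxel_outside_leadfield_rejected(self, leadfield_small):
        with pytest.raises(ValueError, match="effect voxel"):
            CohortConfig(leadfield=leadfield_small, effect_voxels=(9999,))

    def test_default_effect_voxels_are_superomedial(self, leadfield_medium):
        coords = leadfield_medium.voxel_coords
        vox = default_effect_voxels(leadfield_medium)
        assert len(vox) >= 1
        assert np.all(coords[list(vox), 2] == coords[:, 2].max())
        assert np.all(np.abs(coords[list(vox), 0]) == 0)

    def test_occipital_voxel_is_most_posterior(self, leadfield_medium):
        coords = leadfield_medium.voxel_coords
        assert coords[occipital_voxel(leadfield_medium), 1] == coords[:, 1].min()


class TestEnvelope:
    def test_realized_cv_matches_target(self):
        rng = np.random.default_rng(0)
        for cv in (0.2, 0.5, 0.8):
            env = _lognormal_envelope(rng, cv, 20_000)
            assert env.std() / env.mean() == pytest.approx(cv, rel=0.1)
            assert env.mean() == pytest.approx(1.0, rel=0.05)

    def test_zero_cv_is_constant(self):
        env = _lognormal_envelope(np.random.default_rng(0), 0.0, 100)
        assert np.all(env == 1.0)


class TestGeneration:
    def test_same_seed_bitwise_identical(self, leadfield_small):
        cfg = CohortConfig(leadfield=leadfield_small, duration=5.0)
        a = generate_subject(cfg, "responder", 123)
        b = generate_subject(cfg, "responder", 123)
        assert np.array_equal(a.data, b.data)

    def test_cohort_shape_and_determinism(self, leadfield_small):
        cfg = CohortConfig(
            leadfield=leadfield_small, n_responders=15, n_nonresponders=19,
            duration=3.0, seed=5,
        )
        recs, truth = generate_cohort(cfg)
        assert len(recs) == 34
        assert truth.labels.count("responder") == 15
        recs2, _ = generate_cohort(cfg)
        for a, b in zip(recs, recs2):
            assert np.array_equal(a.data, b.data)

    def test_realized_cohort_cv_tracks_group_targets(self, leadfield_small):
        cfg = CohortConfig(
            leadfield=leadfield_small, n_responders=3, n_nonresponders=3,
            duration=400.0, seed=2,
        )
        _, truth = generate_cohort(cfg)
        cvs = np.array(truth.realized_envelope_cv)
        resp = np.array([l == "responder" for l in truth.labels])
        assert np.allclose(cvs[resp], 0.8, rtol=0.15)
        assert np.allclose(cvs[~resp], 0.2, rtol=0.15)

    def test_unknown_group_rejected(self, leadfield_small):
        cfg = CohortConfig(leadfield=leadfield_small, duration=3.0)
        with pytest.raises(ValueError, match="group"):
            generate_subject(cfg, "control", 0)


@pytest.fixture(scope="module")
def filt(eloreta_filter_medium):
    return eloreta_filter_medium


class TestPlantedEffect:
    def test_constant_envelope_gives_near_zero_npv(self, leadfield_medium, filt):
        """No planted instability, no noise: beta NPV at the source is tiny."""
        cfg = CohortConfig(
            leadfield=leadfield_medium, duration=46.0,
            envelope_cv_responder=0.0, envelope_cv_nonresponder=0.0,
            background_sources=0, sensor_noise_sd=0.0, alpha_moment=0.0,
        )
        rec = generate_subject(cfg, "responder", 0)
        npv = beta_npv_at_planted(rec, filt, cfg.resolved_effect_voxels())
        assert npv < 0.05

    def test_responder_exceeds_nonresponder_in_beta(self, leadfield_medium, filt):
        """Default CV contrast, noise off: responder beta NPV wins >= 19/20 pairs."""
        wins = 0
        for seed in range(20):
            cfg = CohortConfig(
                leadfield=leadfield_medium, duration=46.0, sensor_noise_sd=0.0,
            )
            vox = cfg.resolved_effect_voxels()
            r = beta_npv_at_planted(
                generate_subject(cfg, "responder", 1000 + seed), filt, vox)
            n = beta_npv_at_planted(
                generate_subject(cfg, "nonresponder", 2000 + seed), filt, vox)
            wins += r > n
        assert wins >= 19

    def test_contrast_is_localized(self, leadfield_medium, filt):
        """Mean beta NPV difference peaks at (or adjacent to) a planted voxel."""
        cfg = CohortConfig(
            leadfield=leadfield_medium, n_responders=6, n_nonresponders=6,
            duration=60.0, sensor_noise_sd=0.5, background_sources=10, seed=11,
        )
        recs, truth = generate_cohort(cfg)
        maps = []
        for rec in recs:
            rec = apply_average_reference(rec)
            series = band_power_timecourse(filt, segment_recording(rec), fs=rec.fs)
            maps.append(npv_map(series).npv)
        maps = np.stack(maps)
        resp = np.array([l == "responder" for l in truth.labels])
        diff = maps[resp, :, 3].mean(0) - maps[~resp, :, 3].mean(0)
        coords = leadfield_medium.voxel_coords
        d = min(
            np.max(np.abs(coords[diff.argmax()] - coords[pv]))
            for pv in truth.effect_voxels
        )
        assert d <= 30.0  # one grid step
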