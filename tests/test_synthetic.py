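"""Synthetic generator: feature tables, MIX epochs and marked recordings."""

import numpy as np
import pytest

from udseeg import (
    ChannelProfile,
    GeneratorConfig,
    NUDS,
    UDS,
    generate_epoch_signals,
    generate_feature_table,
    generate_marked_recording,
    mix_process,
    sample_entropy,
)
from udseeg.profiles import CHANNELS_10_20, REVERSED_CHANNELS
from udseeg.synthetic import mix_p_from_profiles


class TestFeatureTable:
    def test_shape_labels_and_block_structure(self, profiles):
        fm = generate_feature_table(profiles, 800, seed=42)
        assert fm.values.shape == (1600, 30)
        assert list(fm.channel_labels) == list(CHANNELS_10_20)
        assert (fm.labels[:800] == UDS).all() and (fm.labels[800:] == NUDS).all()
        assert fm.participant_ids.max() == 15  # 16 participants round-robin

    def test_empty_table_keeps_header(self, profiles):
        fm = generate_feature_table(profiles, 0, seed=0)
        assert fm.values.shape == (0, 30)
        assert list(fm.channel_labels) == list(CHANNELS_10_20)

    def test_column_mean_within_clt_bound(self, profiles):
        # C3 in the unfavorable class: mean 0.424, sd 0.127, n=800
        fm = generate_feature_table(profiles, 800, seed=7)
        j = list(CHANNELS_10_20).index("C3")
        c3_uds = fm.values[fm.labels == UDS, j]
        assert abs(c3_uds.mean() - 0.424) < 3 * 0.127 / np.sqrt(800)

    def test_same_seed_bit_identical(self, profiles):
        a = generate_feature_table(profiles, 50, seed=9)
        b = generate_feature_table(profiles, 50, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError, match="SD"):
            ChannelProfile("C3", 0.4, 0.0, 0.5, 0.1)

    def test_negative_count_rejected(self, profiles):
        with pytest.raises(ValueError):
            generate_feature_table(profiles, -1, seed=0)

    def test_duplicate_channel_rejected(self):
        p = ChannelProfile("C3", 0.4, 0.1, 0.5, 0.1)
        with pytest.raises(ValueError, match="unique"):
            generate_feature_table([p, p], 10, seed=0)

    def test_aggregate_sign_pattern_matches_profiles(self, profiles):
        # Population signs (25 channels lower under UDS, 5 reversed) emerge
        # at large n; single study-size draws leave marginal channels (FP2,
        # population gap 0.002) at chance.
        fm = generate_feature_table(profiles, 200_000, seed=11)
        diff = (
            fm.values[fm.labels == NUDS].mean(axis=0)
            - fm.values[fm.labels == UDS].mean(axis=0)
        )
        reversed_obs = {
            ch for ch, d in zip(fm.channel_labels, diff) if d < 0
        }
        assert reversed_obs == set(REVERSED_CHANNELS)
        assert len(REVERSED_CHANNELS) == 5


class TestMixProcess:
    def test_zero_p_is_periodic_with_low_sampen(self, rng):
        # A smoothly varying sinusoid is not exactly self-matching at the
        # 0.2*SD tolerance (mirror-phase templates diverge at length m+1),
        # so its SampEn is small but nonzero — far below any noisy signal.
        x = mix_process(1000, 0.0, rng)
        se_periodic = sample_entropy(x, m=2, r=0.2)
        se_noise = sample_entropy(mix_process(1000, 1.0, rng), m=2, r=0.2)
        assert se_periodic < 0.3
        assert se_periodic < 0.2 * se_noise

    def test_probability_bounds_validated(self, rng):
        with pytest.raises(ValueError):
            mix_process(100, 1.5, rng)

    def test_calibration_preserves_class_ordering(self, profiles):
        p_uds = mix_p_from_profiles(profiles, UDS)
        p_nuds = mix_p_from_profiles(profiles, NUDS)
        for prof, pu, pn in zip(profiles, p_uds, p_nuds):
            if prof.uds_mean < prof.nuds_mean:
                assert pu < pn
            elif prof.uds_mean > prof.nuds_mean:
                assert pu > pn


class TestEpochSignals:
    def test_study_scale_epoch_counts(self, profiles):
        cfg = GeneratorConfig(
            n_subjects=16, events_per_condition=50, fs=1000.0, epoch_len=120, seed=1
        )
        es = generate_epoch_signals(cfg)
        assert es.n_epochs == 1600
        assert (es.labels == UDS).sum() == 800
        assert (es.labels == NUDS).sum() == 800
        assert es.data.shape == (1600, 30, 120)

    def test_larger_mix_p_gives_larger_sampen(self):
        # single-channel C3-style setup with a clear regularity gap
        prof = [ChannelProfile("C3", 0.424, 0.127, 0.534, 0.159)]
        cfg = GeneratorConfig(
            n_subjects=1, events_per_condition=100, epoch_len=300, seed=21,
            mix_p_uds=0.2, mix_p_nuds=0.6, profiles=prof,
        )
        es = generate_epoch_signals(cfg)
        se = np.array([sample_entropy(row[0]) for row in es.data])
        assert se[es.labels == UDS].mean() < se[es.labels == NUDS].mean()


class TestMarkedRecording:
    def test_marker_counts_and_classes(self):
        cfg = GeneratorConfig(n_subjects=1, events_per_condition=50, seed=4,
                              artifact_rate=0.0)
        rec = generate_marked_recording(cfg)
        labs = [lab for _, lab in rec.markers]
        assert labs.count(UDS) == 50 and labs.count(NUDS) == 50

    def test_clean_config_stays_inside_amplitude_bound(self):
        cfg = GeneratorConfig(n_subjects=1, events_per_condition=10, seed=4,
                              artifact_rate=0.0, drift_slope=0.0)
        rec = generate_marked_recording(cfg)
        assert np.abs(rec.data).max() <= 50.0

    def test_artifact_positions_recorded_and_large(self):
        cfg = GeneratorConfig(n_subjects=1, events_per_condition=20, seed=8,
                              artifact_rate=1.0, drift_slope=0.0)
        rec = generate_marked_recording(cfg)
        assert len(rec.artifacts) == 40  # every marker window hit
        for chan, sample in rec.artifacts:
            assert abs(rec.data[chan, sample]) > 50.0

    def test_too_small_marker_spacing_rejected(self):
        cfg = GeneratorConfig(n_subjects=1, events_per_condition=5,
                              marker_spacing_s=0.5, seed=0)
        with pytest.raises(ValueError, match="spacing"):
            generate_marked_recording(cfg)

    def test_same_seed_bit_identical(self):
        cfg = GeneratorConfig(n_subjects=1, events_per_condition=5, seed=13)
        a = generate_marked_recording(cfg)
        b = generate_marked_recording(cfg)
        assert np.array_equal(a.data, b.data)
        assert a.markers == b.markers and a.artifacts == b.artifacts
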