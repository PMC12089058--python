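"""Synthetic session generator: geometry, protocol, generative model, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import periodogram

import fnirsbci as fb
from fnirsbci import synth
from fnirsbci.synth import (
    HBO,
    HBR,
    LATERAL,
    MEDIAL,
    REST,
    TASK_A,
    TASK_B,
)


class TestProbeLayout:
    def test_default_geometry(self, layout):
        assert len(layout.long_positions) == 6
        assert len(layout.short_positions) == 2
        assert all(p.distance_cm == 1.5 for p in layout.short_positions)
        long_d = sorted(p.distance_cm for p in layout.long_positions)
        assert long_d == [3.0, 3.0, 3.0, 3.0, 3.61, 3.61]
        for side in (LATERAL, MEDIAL):
            assert sum(p.side == side for p in layout.long_positions) == 3

    def test_short_map_covers_all_longs(self, layout):
        mapped = sorted(pid for trip in layout.short_map.values() for pid in trip)
        assert mapped == sorted(p.id for p in layout.long_positions)
        assert all(len(trip) == 3 for trip in layout.short_map.values())

    def test_invalid_layouts_rejected(self):
        pos = list(fb.make_default_layout().source_positions)
        bad = [synth.SourcePosition(p.id, p.side, 2.0 if p.side == "SHORT_LATERAL" else p.distance_cm) for p in pos]
        with pytest.raises(ValueError, match="1.5 cm"):
            synth.ProbeLayout(tuple(bad), short_map={7: (1, 2, 3), 8: (4, 5, 6)})
        with pytest.raises(ValueError, match="short_map"):
            synth.ProbeLayout(tuple(pos), short_map={7: (1, 2, 4), 8: (3, 5, 6)})


class TestTaskProtocol:
    def test_schedule_arithmetic(self):
        proto = fb.make_protocol(300)
        assert len(proto.blocks) == 12
        assert proto.total_duration_s == 3 * (300 + 120 + 300 + 120)
        rests = [b for b in proto.blocks if b.task == REST]
        assert all(b.duration_s == 120 for b in rests)
        assert proto.train_groups == (0, 1)
        assert proto.test_groups == (2,)
        for g in range(3):
            tasks = [b.task for b in proto.blocks if b.group == g and b.task != REST]
            assert tasks == [TASK_A, TASK_B]

    def test_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError):
            fb.make_protocol(0)
        with pytest.raises(ValueError):
            fb.make_protocol(-5)

    @settings(max_examples=25, deadline=None)
    @given(duration=st.floats(10.0, 600.0), fs=st.floats(1.0, 20.0))
    def test_labels_tile_sample_axis_exactly(self, duration, fs):
        proto = fb.make_protocol(duration)
        labels, groups = proto.sample_arrays(fs)
        counts = proto.block_samples(fs)
        assert len(labels) == len(groups) == sum(counts)
        assert counts == [int(np.floor(b.duration_s * fs)) for b in proto.blocks]
        assert set(labels) <= {TASK_A, TASK_B, REST}


class TestGenerateSession:
    def test_determinism(self):
        cfg = fb.SessionConfig(seed=7, task_block_duration_s=60)
        a = fb.generate_session(cfg)
        b = fb.generate_session(cfg)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.labels, b.labels)

    def test_seed_required_and_mode_checked(self):
        with pytest.raises(ValueError, match="seed"):
            fb.generate_session(fb.SessionConfig(seed=None))
        with pytest.raises(ValueError, match="mode"):
            fb.generate_session(fb.SessionConfig(seed=0, mode="NOPE"))

    def test_zero_effect_has_no_task_locked_component(self):
        cfg = fb.SessionConfig(
            seed=5,
            task_block_duration_s=120,
            hbo_effect_uM={(s, t): 0.0 for s in (LATERAL, MEDIAL) for t in (TASK_A, TASK_B)},
            superficial_gain=0.0,
        )
        rec = fb.generate_session(cfg)
        resp = synth.task_response(rec.labels, TASK_A, rec.fs_hz)
        for pos in (1, 4):
            r = np.corrcoef(resp, rec.get_channel(pos, HBO))[0, 1]
            assert abs(r) < 0.1

    def test_long_minus_short_is_pure_task_response(self):
        """With unit superficial gain and no noise, subtracting the short
        channel leaves exactly the task-locked component."""
        cfg = fb.SessionConfig(
            seed=11,
            task_block_duration_s=120,
            superficial_gain=1.0,
            white_sd_uM=0.0,
            task_oscillation_gain=0.0,
            between_participant_sd=0.0,
        )
        rec = fb.generate_session(cfg)
        labels = rec.labels
        for side, short_pos, long_pos in ((LATERAL, 7, 1), (MEDIAL, 8, 4)):
            expected = sum(
                cfg.hbo_effect_uM[(side, task)] * synth.task_response(labels, task, cfg.fs_hz)
                for task in (TASK_A, TASK_B)
            )
            diff = rec.get_channel(long_pos, HBO) - rec.get_channel(short_pos, HBO)
            assert np.allclose(diff, expected, atol=1e-10)

    def test_short_channels_carry_no_task_signal(self):
        cfg = fb.SessionConfig(seed=2, task_block_duration_s=120, white_sd_uM=1e-6)
        rec = fb.generate_session(cfg)
        resp = synth.task_response(rec.labels, TASK_A, cfg.fs_hz)
        for pos in (7, 8):
            r = np.corrcoef(resp, rec.get_channel(pos, HBO))[0, 1]
            assert abs(r) < 0.1

    def test_hbr_opposite_sign_and_smaller(self):
        cfg = fb.SessionConfig(
            seed=4, task_block_duration_s=120, white_sd_uM=0.0,
            superficial_gain=0.0, task_oscillation_gain=0.0, between_participant_sd=0.0,
        )
        rec = fb.generate_session(cfg)
        hbo = rec.get_channel(4, HBO)
        hbr = rec.get_channel(4, HBR)
        assert np.allclose(hbr, -0.3 * hbo, atol=1e-12)

    def test_superficial_spectral_peaks(self):
        """Periodogram of a short channel peaks at the configured frequencies."""
        cfg = fb.SessionConfig(seed=9, task_block_duration_s=300, white_sd_uM=0.0)
        rec = fb.generate_session(cfg)
        f, p = periodogram(rec.get_channel(7, HBO), fs=cfg.fs_hz)
        for _, (amp, freq) in cfg.oscillations.items():
            if amp == 0:
                continue
            band = (f > freq * 0.8) & (f < freq * 1.25)
            outside = (f > freq * 1.6) & (f < freq * 2.4) if freq < 1.2 else (f > 2.3)
            assert p[band].max() > 10 * p[outside].max()


class TestPermutation:
    def test_permute_blocks_preserves_data_and_label_multiset(self, session):
        perm = synth.permute_task_blocks(session, seed=42)
        assert np.array_equal(perm.data, session.data)
        assert sorted(perm.labels) == sorted(session.labels)
        assert np.array_equal(perm.labels == REST, session.labels == REST)


class TestSessionIO:
    def test_csv_round_trip(self, tmp_path, session):
        path = tmp_path / "s.csv"
        fb.write_session(session, path, format="CSV")
        back = fb.read_session(path, format="CSV")
        assert np.allclose(back.data, session.data)
        assert np.array_equal(back.labels, session.labels)
        assert np.array_equal(back.groups, session.groups)
        assert back.fs_hz == session.fs_hz
        assert back.participant_id == session.participant_id
        assert back.channel_names == session.channel_names

    def test_csv_missing_label_column_errors(self, tmp_path, session):
        path = tmp_path / "s.csv"
        fb.write_session(session, path)
        text = path.read_text().replace("label", "lbl")
        path.write_text(text)
        with pytest.raises(ValueError, match="label"):
            fb.read_session(path)

    def test_snirf_round_trip(self, tmp_path, session):
        path = tmp_path / "s.snirf"
        fb.write_session(session, path, format="SNIRF")
        back = fb.read_session(path, format="SNIRF")
        assert np.allclose(back.data, session.data, atol=1e-9)
        assert np.array_equal(back.labels, session.labels)
        assert back.channel_names == session.channel_names
        assert abs(back.fs_hz - session.fs_hz) < 1e-6

    def test_raw_mode_round_trips_with_baseline(self, tmp_path, layout, protocol):
        cfg = fb.SessionConfig(seed=6, task_block_duration_s=60, mode="RAW_INTENSITY")
        rec = fb.generate_session(cfg, layout, protocol=fb.make_protocol(60))
        path = tmp_path / "raw.csv"
        fb.write_session(rec, path)
        back = fb.read_session(path)
        assert back.mode == "RAW_INTENSITY"
        assert np.allclose(back.baseline_intensity, rec.baseline_intensity)

    def test_unknown_format_rejected(self, tmp_path, session):
        with pytest.raises(ValueError):
            fb.write_session(session, tmp_path / "x", format="EDF")


class TestCohort:
    def test_counter_based_seeds_are_stable(self):
        base = fb.SessionConfig(task_block_duration_s=60)
        small = fb.generate_cohort(2, 99, base)
        larger = fb.generate_cohort(3, 99, base)
        for a, b in zip(small, larger):
            assert np.array_equal(a.data, b.data)
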