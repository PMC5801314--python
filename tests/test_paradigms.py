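"""Tone synthesis and stimulus-sequence structure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmndecay.paradigms import (
    DEVIANT_FAMILIES,
    GapSpec,
    ParadigmSequence,
    StimulusEvent,
    ToneSpec,
    export_sequence,
    family_of,
    generate_memtra_sequence,
    generate_opt1_sequence,
    read_event_table,
    standard_and_deviant_specs,
    synthesize_tone,
    tone_duration_ms,
)

FS = 48_000.0


# ---------------------------------------------------------------------------
# tones

class TestToneSpecs:
    def test_catalogue_parameters(self):
        specs = standard_and_deviant_specs()
        assert set(specs) == {
            "standard", "duration", "gap", "frequency_high", "frequency_low",
            "intensity_loud", "intensity_soft", "location_left", "location_right",
        }
        std = specs["standard"]
        assert std.partial_freqs_hz == (500.0, 1000.0, 1500.0)
        assert std.partial_level_offsets_db == (0.0, -3.0, -6.0)
        assert std.duration_ms == 75.0 and std.rise_fall_ms == 5.0
        assert std.intensity_offset_db == 0.0
        assert specs["duration"].duration_ms == 25.0  # 50 ms shorter
        assert specs["frequency_high"].partial_freqs_hz == (550.0, 1100.0, 1650.0)
        assert specs["frequency_low"].partial_freqs_hz == (450.0, 900.0, 1350.0)
        assert specs["intensity_loud"].intensity_offset_db == 10.0
        assert specs["intensity_soft"].intensity_offset_db == -10.0
        assert specs["location_left"].itd_us == -800.0
        assert specs["location_right"].itd_us == 800.0
        assert specs["gap"].gap == GapSpec(7.0, 1.0, True)

    def test_rendered_lengths(self):
        specs = standard_and_deviant_specs()
        assert synthesize_tone(specs["standard"], FS).shape == (3600, 2)  # 75 ms
        assert synthesize_tone(specs["duration"], FS).shape == (1200, 2)  # 25 ms

    def test_intensity_rms_ratio(self):
        specs = standard_and_deviant_specs()
        rms = lambda x: float(np.sqrt((x**2).mean()))
        std = rms(synthesize_tone(specs["standard"], FS))
        loud = rms(synthesize_tone(specs["intensity_loud"], FS))
        soft = rms(synthesize_tone(specs["intensity_soft"], FS))
        assert loud / std == pytest.approx(10 ** 0.5, rel=1e-2)
        assert soft / std == pytest.approx(10 ** -0.5, rel=1e-2)

    def test_gap_center_silence(self):
        gap = synthesize_tone(standard_and_deviant_specs()["gap"], FS)[:, 0]
        n = gap.size
        assert gap[n // 2] == 0.0
        # fully silent span: 7 ms minus the two 1-ms ramps
        silent = np.flatnonzero(np.abs(gap) == 0.0)
        runs = np.split(silent, np.flatnonzero(np.diff(silent) > 1) + 1)
        center_run = max(runs, key=len)
        assert len(center_run) >= round(5e-3 * FS)
        assert n // 2 in center_run

    def test_itd_whole_sample_delay(self):
        specs = standard_and_deviant_specs()
        d = round(800e-6 * FS)  # 38 samples at 48 kHz
        right = synthesize_tone(specs["location_right"], FS)
        np.testing.assert_allclose(right[d:, 0], right[: right.shape[0] - d, 1])
        left = synthesize_tone(specs["location_left"], FS)
        np.testing.assert_allclose(left[d:, 1], left[: left.shape[0] - d, 0])

    def test_ramps_start_and_end_at_zero(self):
        x = synthesize_tone(standard_and_deviant_specs()["standard"], FS)[:, 0]
        assert x[0] == 0.0
        assert abs(x[-1]) < 1e-3

    @given(
        x=st.floats(min_value=-10, max_value=10),
        y=st.floats(min_value=-10, max_value=10),
    )
    @settings(max_examples=20, deadline=None)
    def test_amplitude_linearity_in_db(self, x, y):
        a = synthesize_tone(ToneSpec(intensity_offset_db=x + y), 8000.0)
        b = synthesize_tone(ToneSpec(intensity_offset_db=x), 8000.0) * 10 ** (y / 20)
        np.testing.assert_allclose(a, b, atol=1e-10)

    @pytest.mark.parametrize(
        "spec, rate",
        [
            (ToneSpec(duration_ms=0.0), FS),
            (ToneSpec(rise_fall_ms=40.0), FS),  # 2*40 > 75
            (ToneSpec(partial_level_offsets_db=(1.0, -3.0, -6.0)), FS),
            (ToneSpec(gap=GapSpec(gap_length_ms=70.0)), FS),
            (ToneSpec(), 2000.0),  # 1500 Hz partial above Nyquist
        ],
    )
    def test_validation_errors(self, spec, rate):
        with pytest.raises(ValueError):
            synthesize_tone(spec, rate)


# ---------------------------------------------------------------------------
# Optimum-1

class TestOpt1:
    def test_counts_and_alternation(self):
        seq = generate_opt1_sequence(seed=3)
        assert len(seq.events) == 1845
        for block in seq.blocks():
            assert len(block) == 615
            assert all(e.kind == "standard" for e in block[:15])
            post = block[15:]
            # every second post-initial tone is a standard (even index)
            for j, e in enumerate(post):
                assert (e.kind == "standard") == (j % 2 == 0)
            assert sum(e.kind == "standard" for e in post) == 300
            # each family holds exactly 60 of the 600 alternating slots (10 %)
            fams = [family_of(e.kind) for e in post if e.kind != "standard"]
            for fam in DEVIANT_FAMILIES:
                assert fams.count(fam) == 60
            # consecutive deviants differ in family
            assert all(a != b for a, b in zip(fams, fams[1:]))

    def test_family_totals_and_subvariants(self):
        seq = generate_opt1_sequence(seed=9)
        kinds = [e.kind for e in seq.events]
        assert sum(family_of(k) == "duration" for k in kinds) == 180  # 3 x 60
        assert kinds.count("frequency_high") == kinds.count("frequency_low") == 90
        assert kinds.count("intensity_loud") == kinds.count("intensity_soft") == 90
        assert kinds.count("location_left") == kinds.count("location_right") == 90

    def test_fixed_soa_onsets(self):
        seq = generate_opt1_sequence(seed=0)
        for block in seq.blocks():
            onsets = np.array([e.onset_s for e in block])
            np.testing.assert_allclose(np.diff(onsets), 0.5)


# ---------------------------------------------------------------------------
# Memory-Trace

class TestMemTra:
    def test_counts_and_probabilities(self):
        seq = generate_memtra_sequence(seed=4)
        assert len(seq.events) == 462
        fams = [family_of(e.kind) for e in seq.events]
        assert fams.count("standard") == 306       # 66.2 %
        assert fams.count("duration") == 78        # 16.9 %
        assert fams.count("frequency") == 78       # 16.9 %
        for block in seq.blocks():
            assert len(block) == 154
            assert all(e.kind == "standard" for e in block[:15])

    def test_every_deviant_follows_standard_at_3s(self):
        seq = generate_memtra_sequence(seed=4)
        for block in seq.blocks():
            for prev, ev in zip(block, block[1:]):
                if ev.kind != "standard":
                    assert prev.kind == "standard"
                    assert ev.isi_before_s == pytest.approx(3.0)
                    gap = ev.onset_s - (prev.onset_s + tone_duration_ms(prev.kind) / 1000)
                    assert gap == pytest.approx(3.0)

    def test_interdeviant_run_lengths(self):
        seq = generate_memtra_sequence(seed=12)
        for block in seq.blocks():
            post = block[15:]
            runs, run = [], 0
            for e in post:
                if e.kind == "standard":
                    run += 1
                else:
                    runs.append(run)
                    run = 0
            assert set(runs) <= {1, 2, 3}
            assert sum(runs) == 87
            assert len(runs) == 52

    def test_standard_isis_from_menu(self):
        seq = generate_memtra_sequence(seed=2)
        menu = {0.5, 1.5, 3.0}
        for block in seq.blocks():
            for e in block[1:]:
                if e.kind == "standard":
                    assert e.isi_before_s in menu

    def test_infeasible_composition_raises(self):
        with pytest.raises(ValueError, match="cannot place"):
            generate_memtra_sequence(seed=0, deviants_per_family=10, interleaved_standards=87)


# ---------------------------------------------------------------------------
# determinism & export

@pytest.mark.parametrize("gen", [generate_opt1_sequence, generate_memtra_sequence])
def test_identical_seeds_identical_tables(gen):
    a, b = gen(seed=42).to_frame(), gen(seed=42).to_frame()
    assert a.equals(b)
    assert not gen(seed=43).to_frame().equals(a)


@given(seed=st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=10, deadline=None)
def test_memtra_structure_holds_for_any_seed(seed):
    seq = generate_memtra_sequence(seed=seed)
    assert len(seq.events) == 462
    for block in seq.blocks():
        for prev, ev in zip(block, block[1:]):
            if ev.kind != "standard":
                assert prev.kind == "standard" and ev.isi_before_s == 3.0


def test_event_table_roundtrip(tmp_path):
    seq = generate_opt1_sequence(seed=1)
    paths = export_sequence(seq, out_prefix=tmp_path / "opt1", write_audio=False)
    back = read_event_table(paths["events"])
    assert back.paradigm == "opt1" and back.seed == 1
    assert len(back.events) == 1845
    for a, b in zip(seq.events, back.events):
        assert a.kind == b.kind and a.block_index == b.block_index
        assert a.onset_s == b.onset_s
        assert a.isi_before_s == b.isi_before_s or (
            math.isnan(a.isi_before_s) and math.isnan(b.isi_before_s)
        )


def test_audio_export_duration(tmp_path):
    from scipy.io import wavfile

    events = [
        StimulusEvent(0.0, "standard", math.nan, 0),
        StimulusEvent(0.5, "standard", 0.425, 0),
        StimulusEvent(1.0, "duration", 0.425, 0),
    ]
    seq = ParadigmSequence("opt1", events, seed=0, soa_s=0.5)
    fs = 8000.0
    paths = export_sequence(seq, sample_rate=fs, out_prefix=tmp_path / "mini")
    rate, audio = wavfile.read(paths["block0"])
    assert rate == fs
    assert audio.shape == (round((1.0 + 0.025) * fs), 2)  # last onset + 25 ms tone
    assert np.abs(audio[round(0.02 * fs)]).max() > 0  # tone present at start
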