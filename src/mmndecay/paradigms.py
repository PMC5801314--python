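"""Auditory stimuli and sequences for the two mismatch-negativity paradigms.

Two passive paradigms probe the auditory sensory memory trace at different
time scales:

* **Optimum-1 (opt1)** — a short-SOA (0.5 s) multi-deviant sequence in which
  every second tone is the standard and five deviant families (duration, gap,
  frequency, intensity, location) share the deviant slots.  It measures the
  MMN after a short interstimulus interval, i.e. auditory discrimination.
* **Memory-Trace (memtra)** — a long-ISI sequence in which every deviant
  follows a standard after exactly 3 s of silence, with one to three
  standards between consecutive deviants.  It measures the persistence of
  the memory trace for the standard tone over 3 s.

The standard tone is a harmonic complex of three sinusoidal partials
(500/1000/1500 Hz, the second 3 dB and the third 6 dB below the first),
75 ms long with 5 ms linear rise/fall ramps.  Deviants differ in exactly one
feature: 50 ms shorter (duration), a 7-ms central silent gap (gap), all
partials +/-10 % (frequency), +/-10 dB (intensity), or an 800-microsecond
interaural time difference (location).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "GapSpec",
    "ToneSpec",
    "StimulusEvent",
    "ParadigmSequence",
    "DEVIANT_FAMILIES",
    "family_of",
    "tone_duration_ms",
    "synthesize_tone",
    "standard_and_deviant_specs",
    "generate_opt1_sequence",
    "generate_memtra_sequence",
    "export_sequence",
    "read_event_table",
]

#: deviant families, in the fixed order used throughout the package
DEVIANT_FAMILIES = ("duration", "gap", "frequency", "intensity", "location")

#: concrete stimulus kinds (sub-variants split 50/50 within their family)
KINDS = (
    "standard",
    "duration",
    "gap",
    "frequency_high",
    "frequency_low",
    "intensity_loud",
    "intensity_soft",
    "location_left",
    "location_right",
)

_FAMILY_OF = {
    "standard": "standard",
    "duration": "duration",
    "gap": "gap",
    "frequency_high": "frequency",
    "frequency_low": "frequency",
    "intensity_loud": "intensity",
    "intensity_soft": "intensity",
    "location_left": "location",
    "location_right": "location",
}


def family_of(kind: str) -> str:
    """Pool a concrete stimulus kind into its deviant family (or 'standard')."""
    try:
        return _FAMILY_OF[kind]
    except KeyError:
        raise ValueError(f"unknown stimulus kind: {kind!r}") from None


@dataclass(frozen=True)
class GapSpec:
    """A silent gap centred in the tone, with its own short ramps."""

    gap_length_ms: float = 7.0
    gap_rise_fall_ms: float = 1.0
    centered: bool = True


@dataclass(frozen=True)
class ToneSpec:
    """Acoustic definition of one stimulus.

    ``partial_level_offsets_db`` are attenuations of the second and third
    partial relative to the first (whose offset is fixed at 0 dB);
    ``intensity_offset_db`` shifts the loudness of the whole tone relative to
    the standard; ``itd_us`` is a signed interaural time difference
    (positive = right ear leads, i.e. the tone is lateralised to the right).
    """

    partial_freqs_hz: tuple[float, float, float] = (500.0, 1000.0, 1500.0)
    partial_level_offsets_db: tuple[float, float, float] = (0.0, -3.0, -6.0)
    duration_ms: float = 75.0
    rise_fall_ms: float = 5.0
    gap: Optional[GapSpec] = None
    intensity_offset_db: float = 0.0
    itd_us: float = 0.0

    def validate(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.rise_fall_ms < 0:
            raise ValueError("rise_fall_ms must be non-negative")
        if 2 * self.rise_fall_ms > self.duration_ms:
            raise ValueError("rise/fall ramps do not fit inside the tone")
        if self.partial_level_offsets_db[0] != 0.0:
            raise ValueError("first partial defines the 0 dB reference")
        if self.gap is not None:
            if self.gap.gap_length_ms <= 0:
                raise ValueError("gap_length_ms must be positive")
            if 2 * self.gap.gap_rise_fall_ms > self.gap.gap_length_ms:
                raise ValueError("gap ramps do not fit inside the gap")
            if self.gap.gap_length_ms >= self.duration_ms - 2 * self.rise_fall_ms:
                raise ValueError("gap does not fit inside the tone")


def tone_duration_ms(kind: str) -> float:
    """Nominal duration of a stimulus kind (duration deviants are 25 ms)."""
    return 25.0 if kind == "duration" else 75.0


def synthesize_tone(spec: ToneSpec, sample_rate: float = 48_000.0) -> np.ndarray:
    """Render a ToneSpec to a stereo waveform of shape ``(n_samples, 2)``.

    The three partials are summed with their dB offsets, normalised so the
    standard tone peaks near +/-1, ramped linearly at onset/offset, optionally
    gated by a centred silent gap, scaled by ``intensity_offset_db`` and
    lateralised by delaying one channel by ``round(|itd_us| * fs / 1e6)``
    whole samples.
    """
    spec.validate()
    nyquist = sample_rate / 2.0
    if max(spec.partial_freqs_hz) >= nyquist:
        raise ValueError(
            f"highest partial {max(spec.partial_freqs_hz)} Hz is not below "
            f"the Nyquist frequency {nyquist} Hz"
        )

    n = round(spec.duration_ms * sample_rate / 1000.0)
    t = np.arange(n) / sample_rate
    amps = 10.0 ** (np.asarray(spec.partial_level_offsets_db) / 20.0)
    x = np.zeros(n)
    for f, a in zip(spec.partial_freqs_hz, amps):
        x += a * np.sin(2 * np.pi * f * t)
    x /= amps.sum()  # standard tone peak ~ 1 before intensity offset

    env = np.ones(n)
    ramp = round(spec.rise_fall_ms * sample_rate / 1000.0)
    if ramp > 0:
        env[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
        env[n - ramp:] = np.linspace(1.0, 0.0, ramp + 1)[1:]

    if spec.gap is not None:
        g = round(spec.gap.gap_length_ms * sample_rate / 1000.0)
        gr = round(spec.gap.gap_rise_fall_ms * sample_rate / 1000.0)
        start = (n - g) // 2  # centred
        gate = np.zeros(g)
        if gr > 0:
            gate[:gr] = np.linspace(1.0, 0.0, gr, endpoint=False)
            gate[g - gr:] = np.linspace(0.0, 1.0, gr + 1)[1:]
        env[start:start + g] *= gate

    x = x * env * 10.0 ** (spec.intensity_offset_db / 20.0)

    left = x.copy()
    right = x.copy()
    d = round(abs(spec.itd_us) * sample_rate / 1e6)
    if d > 0:
        if spec.itd_us > 0:  # right leads -> delay left channel
            left = np.concatenate([np.zeros(d), left[:-d]])
        else:
            right = np.concatenate([np.zeros(d), right[:-d]])
    return np.column_stack([left, right])


def standard_and_deviant_specs() -> dict[str, ToneSpec]:
    """The nine tone definitions used by both paradigms."""
    std = ToneSpec()
    return {
        "standard": std,
        "duration": replace(std, duration_ms=25.0),  # 50 ms shorter
        "gap": replace(std, gap=GapSpec()),
        "frequency_high": replace(std, partial_freqs_hz=(550.0, 1100.0, 1650.0)),
        "frequency_low": replace(std, partial_freqs_hz=(450.0, 900.0, 1350.0)),
        "intensity_loud": replace(std, intensity_offset_db=10.0),
        "intensity_soft": replace(std, intensity_offset_db=-10.0),
        "location_left": replace(std, itd_us=-800.0),
        "location_right": replace(std, itd_us=800.0),
    }


@dataclass(frozen=True)
class StimulusEvent:
    onset_s: float          # time from block start (tone onset)
    kind: str               # one of KINDS
    isi_before_s: float     # silence since previous tone offset (NaN if first)
    block_index: int


@dataclass
class ParadigmSequence:
    paradigm: str                      # "opt1" | "memtra"
    events: list[StimulusEvent]
    seed: int
    soa_s: Optional[float] = None      # opt1 only
    isi_menu_s: Optional[tuple[float, ...]] = None  # memtra only

    def blocks(self) -> list[list[StimulusEvent]]:
        out: dict[int, list[StimulusEvent]] = {}
        for ev in self.events:
            out.setdefault(ev.block_index, []).append(ev)
        return [out[b] for b in sorted(out)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": [e.block_index for e in self.events],
                "onset_s": [e.onset_s for e in self.events],
                "kind": [e.kind for e in self.events],
                "isi_before_s": [e.isi_before_s for e in self.events],
            }
        )


# ---------------------------------------------------------------------------
# sequence generation

def _no_adjacent_repeat(counts: dict[str, int], rng: np.random.Generator) -> list[str]:
    """Random sequence realising ``counts`` with no two equal neighbours.

    Greedy with a forcing rule: whenever some label holds at least half of
    the remaining slots it must be placed next, otherwise labels are drawn
    with probability proportional to their remaining count.  This always
    succeeds when a valid arrangement exists (max count <= ceil(total/2)).
    """
    remaining = dict(counts)
    total = sum(remaining.values())
    if max(remaining.values(), default=0) > (total + 1) // 2:
        raise ValueError("no arrangement without adjacent repeats exists")
    seq: list[str] = []
    prev: Optional[str] = None
    for r in range(total, 0, -1):
        cand = [k for k, c in remaining.items() if c > 0 and k != prev]
        forced = [k for k in cand if remaining[k] >= (r + 1) // 2]
        if forced:
            pick = forced[int(rng.integers(len(forced)))]
        else:
            weights = np.array([remaining[k] for k in cand], dtype=float)
            pick = cand[int(rng.choice(len(cand), p=weights / weights.sum()))]
        seq.append(pick)
        remaining[pick] -= 1
        prev = pick
    return seq


def _subvariants(family: str, n: int, rng: np.random.Generator) -> list[str]:
    """Expand family slots into concrete kinds, 50/50 within the family."""
    pairs = {
        "frequency": ("frequency_high", "frequency_low"),
        "intensity": ("intensity_loud", "intensity_soft"),
        "location": ("location_left", "location_right"),
    }
    if family not in pairs:
        return [family] * n
    a, b = pairs[family]
    kinds = [a] * (n // 2) + [b] * (n - n // 2)
    rng.shuffle(kinds)
    return kinds


def generate_opt1_sequence(
    seed: int,
    n_blocks: int = 3,
    leading_standards: int = 15,
    alternating_events: int = 600,
    soa_s: float = 0.5,
    forbid_family_repeat: bool = True,
) -> ParadigmSequence:
    """Optimum-1 sequence: 3 blocks x (15 standards + 600 alternating events).

    Every second post-initial tone is a standard; the 300 deviant slots per
    block split into 60 per family (deviant-type probability 10 % of the 600
    alternating events); consecutive deviants differ in family by default.
    """
    rng = np.random.default_rng(seed)
    events: list[StimulusEvent] = []
    per_family = alternating_events // 2 // len(DEVIANT_FAMILIES)
    for b in range(n_blocks):
        counts = {f: per_family for f in DEVIANT_FAMILIES}
        if forbid_family_repeat:
            fam_seq = _no_adjacent_repeat(counts, rng)
        else:
            fam_seq = [f for f, c in counts.items() for _ in range(c)]
            rng.shuffle(fam_seq)
        # assign sub-variants per family, preserving the family positions
        slots: dict[str, list[str]] = {
            f: _subvariants(f, fam_seq.count(f), rng) for f in DEVIANT_FAMILIES
        }
        dev_kinds = [slots[f].pop() for f in fam_seq]

        kinds = ["standard"] * leading_standards
        di = iter(dev_kinds)
        for j in range(alternating_events):
            kinds.append("standard" if j % 2 == 0 else next(di))

        prev_kind: Optional[str] = None
        for i, kind in enumerate(kinds):
            onset = i * soa_s
            isi = (
                math.nan
                if prev_kind is None
                else soa_s - tone_duration_ms(prev_kind) / 1000.0
            )
            events.append(StimulusEvent(onset, kind, isi, b))
            prev_kind = kind
    return ParadigmSequence("opt1", events, seed, soa_s=soa_s)


def generate_memtra_sequence(
    seed: int,
    n_blocks: int = 3,
    leading_standards: int = 15,
    deviants_per_family: int = 26,
    interleaved_standards: int = 87,
    isi_menu_s: tuple[float, ...] = (0.5, 1.5, 3.0),
    deviant_isi_s: float = 3.0,
) -> ParadigmSequence:
    """Memory-Trace sequence: 3 blocks x 154 events (462 total).

    Per block: 15 leading standards, then 52 deviants (26 duration, 26
    frequency, half of the latter 10 % higher / half lower), each preceded by
    a pseudorandom run of 1-3 standards (runs sum to 87) and separated from
    its preceding standard by exactly 3 s of silence.  Standards' own ISIs
    are drawn uniformly from ``isi_menu_s``.
    """
    rng = np.random.default_rng(seed)
    n_dev = 2 * deviants_per_family
    lo, hi = 1, 3
    if not (n_dev * lo <= interleaved_standards <= n_dev * hi):
        raise ValueError(
            f"cannot place {interleaved_standards} standards into {n_dev} "
            f"runs of {lo}-{hi}"
        )

    events: list[StimulusEvent] = []
    for b in range(n_blocks):
        # run lengths: start at 1 each, distribute the surplus
        runs = np.full(n_dev, lo)
        surplus = interleaved_standards - n_dev * lo
        while surplus > 0:
            i = int(rng.integers(n_dev))
            if runs[i] < hi:
                runs[i] += 1
                surplus -= 1
        dev_kinds = (
            ["duration"] * deviants_per_family
            + _subvariants("frequency", deviants_per_family, rng)
        )
        rng.shuffle(dev_kinds)

        kinds: list[str] = ["standard"] * leading_standards
        isis: list[float] = [math.nan] + [
            float(rng.choice(isi_menu_s)) for _ in range(leading_standards - 1)
        ]
        for r, dk in zip(runs, dev_kinds):
            for _ in range(int(r)):
                kinds.append("standard")
                isis.append(float(rng.choice(isi_menu_s)))
            kinds.append(dk)
            isis.append(deviant_isi_s)

        onset = 0.0
        prev_dur = 0.0
        for i, (kind, isi) in enumerate(zip(kinds, isis)):
            if i > 0:
                onset = onset + prev_dur + isi
            events.append(StimulusEvent(onset, kind, isi, b))
            prev_dur = tone_duration_ms(kind) / 1000.0
    return ParadigmSequence("memtra", events, seed, isi_menu_s=isi_menu_s)


# ---------------------------------------------------------------------------
# export / import

def export_sequence(
    seq: ParadigmSequence,
    specs: Optional[Mapping[str, ToneSpec]] = None,
    sample_rate: float = 48_000.0,
    out_prefix: str | Path = "paradigm",
    write_audio: bool = True,
) -> dict[str, Path]:
    """Write one stereo WAV per block plus a tab-separated event table.

    The event table (columns block, onset_s, kind, isi_before_s, with a
    ``#``-comment header recording paradigm and seed) round-trips through
    :func:`read_event_table` exactly.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    table = out_prefix.with_suffix(".events.tsv")
    with open(table, "w") as fh:
        fh.write(f"# paradigm={seq.paradigm} seed={seq.seed}\n")
        seq.to_frame().to_csv(fh, sep="\t", index=False)
    paths["events"] = table

    if write_audio:
        if specs is None:
            specs = standard_and_deviant_specs()
        tones = {k: synthesize_tone(s, sample_rate) for k, s in specs.items()}
        for b, block in enumerate(seq.blocks()):
            last = block[-1]
            n = round((last.onset_s + tone_duration_ms(last.kind) / 1000.0) * sample_rate)
            audio = np.zeros((n, 2), dtype=np.float64)
            for ev in block:
                tone = tones[ev.kind]
                i0 = round(ev.onset_s * sample_rate)
                audio[i0:i0 + len(tone)] += tone
            path = out_prefix.parent / f"{out_prefix.name}_block{b}.wav"
            wavfile.write(path, int(sample_rate), audio.astype(np.float32))
            paths[f"block{b}"] = path
    return paths


def read_event_table(path: str | Path) -> ParadigmSequence:
    """Reconstruct a ParadigmSequence from an exported event table."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing metadata header line")
        meta = dict(item.split("=") for item in header[1:].split())
        df = pd.read_csv(fh, sep="\t")
    events = [
        StimulusEvent(float(r.onset_s), str(r.kind), float(r.isi_before_s), int(r.block))
        for r in df.itertuples()
    ]
    paradigm = meta["paradigm"]
    return ParadigmSequence(
        paradigm,
        events,
        seed=int(meta["seed"]),
        soa_s=0.5 if paradigm == "opt1" else None,
        isi_menu_s=(0.5, 1.5, 3.0) if paradigm == "memtra" else None,
    )
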