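"""Vibrotactile stimulus and oddball-sequence synthesis.

Two stimulus families are supported:

* a *frequency–intensity* contrast: 125-ms sinusoidal vibrations with linear
  15-ms onset/offset ramps, standards at 300 Hz and deviants at 200 Hz
  (frequencies in the preferred band of rapidly adapting type-II
  mechanoreceptors);
* a *spectrotemporal* contrast: 125-ms band-limited (40–200 Hz) white-noise
  snippets in which the deviant is a temporal shuffle of the standard's
  pre-filter samples, so the pair shares its amplitude distribution and
  average spectrum but differs in envelope and spectral time course.

Stimuli are assembled into periodic oddball trains (default ``AAAAB`` at an
8 Hz base rate, i.e. a 1.6 Hz deviant rate) looped into 40-s sequences with
one onset marker per stimulus slot.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "StimulusWaveform",
    "OddballSequence",
    "make_sine_stimulus",
    "make_noise_pair",
    "rms_normalize",
    "assemble_sequence",
    "write_wav",
    "write_waveform_tsv",
    "write_markers_tsv",
]

#: default single-stimulus duration in seconds
STIMULUS_DURATION = 0.125
#: default linear ramp duration (each end) in seconds
RAMP_DURATION = 0.015
#: carrier frequencies (Hz) of the frequency–intensity contrast
SINE_FREQ_STANDARD = 300.0
SINE_FREQ_DEVIANT = 200.0
#: pass band (Hz) of the spectrotemporal noise stimuli
NOISE_BAND = (40.0, 200.0)
#: default synthesis rate, samples/s; >= 2x the ~1 kHz mechanoreceptor ceiling
DEFAULT_RATE = 8000.0


@dataclass(frozen=True)
class StimulusWaveform:
    """A single vibration stimulus: sampled amplitude in [-1, 1] plus rate."""

    samples: np.ndarray
    rate: float
    label: str = "A"

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D series")

    @property
    def duration(self) -> float:
        """Duration in seconds (sample count / rate)."""
        return self.samples.size / self.rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate


@dataclass(frozen=True)
class OddballSequence:
    """An assembled periodic oddball train with per-stimulus onset markers."""

    waveform: np.ndarray
    rate: float
    base_rate: float
    pattern: str = "AAAAB"
    n_loops: int = 64
    markers: list = field(default_factory=list)  # (onset time s, label)

    @property
    def oddball_rate(self) -> float:
        """Rate of the deviant stimulus: base rate / pattern length."""
        return self.base_rate / len(self.pattern)

    @property
    def duration(self) -> float:
        return self.waveform.size / self.rate


def _linear_ramp_envelope(n: int, rate: float, ramp: float) -> np.ndarray:
    """Trapezoidal envelope: 0→1 over ``ramp`` s, flat, 1→0 over ``ramp`` s.

    The first and last samples sit exactly at 0 so that concatenated stimuli
    never produce discontinuities.
    """
    t = np.arange(n) / rate
    t_end = (n - 1) / rate
    if ramp <= 0:
        return np.ones(n)
    env = np.minimum.reduce([np.ones(n), t / ramp, (t_end - t) / ramp])
    return np.clip(env, 0.0, 1.0)


def make_sine_stimulus(
    freq: float,
    duration: float = STIMULUS_DURATION,
    rate: float = DEFAULT_RATE,
    ramp: float = RAMP_DURATION,
    label: str = "A",
) -> StimulusWaveform:
    """Unit-amplitude sinusoidal vibration with linear on/off ramps.

    Parameters
    ----------
    freq : float
        Carrier frequency in Hz; must lie below the Nyquist rate.
    duration, rate, ramp : float
        Stimulus duration (s), sample rate (samples/s) and ramp length (s);
        two ramps must fit inside the stimulus (``2 * ramp <= duration``).
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    if freq >= rate / 2:
        raise ValueError(f"carrier {freq} Hz at or above Nyquist ({rate / 2} Hz)")
    if 2 * ramp > duration:
        raise ValueError("ramp longer than half the stimulus duration")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    y = np.sin(2 * np.pi * freq * t) * _linear_ramp_envelope(n, rate, ramp)
    return StimulusWaveform(samples=y, rate=rate, label=label)


def rms_normalize(
    waveforms: list[StimulusWaveform], target_rms: float = 1.0
) -> list[StimulusWaveform]:
    """Scale each waveform so its RMS equals ``target_rms`` exactly.

    A scale-only transform: shapes are preserved. All-zero input is rejected
    because it carries no scale.
    """
    out = []
    for w in waveforms:
        r = w.rms
        if r == 0:
            raise ValueError("cannot RMS-normalize an all-zero waveform")
        out.append(replace(w, samples=w.samples * (target_rms / r)))
    return out


def raw_noise_pair(seed: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Pre-filter white-noise pair: A is Gaussian noise, B a seeded random
    permutation of A's samples (identical amplitude multiset).

    The master seed deterministically yields independent sub-streams for the
    noise draw and for the permutation.
    """
    ss = np.random.SeedSequence(seed)
    rng_noise, rng_perm = (np.random.default_rng(s) for s in ss.spawn(2))
    a = rng_noise.standard_normal(n)
    return a, a[rng_perm.permutation(n)]


def make_noise_pair(
    seed: int,
    duration: float = STIMULUS_DURATION,
    rate: float = DEFAULT_RATE,
    band: tuple[float, float] = NOISE_BAND,
    ramp: float = RAMP_DURATION,
    target_rms: float = 0.25,
    filter_order: int = 4,
) -> tuple[StimulusWaveform, StimulusWaveform]:
    """Generate a matched (standard, deviant) pair of noise stimuli.

    The standard ``A`` is white Gaussian noise; the deviant ``B`` is a seeded
    random permutation of A's pre-filter samples, so both share the same
    amplitude multiset and (on average) the same spectrum while differing in
    envelope and spectral time course. Both are then band-pass filtered
    (zero-phase Butterworth of design order ``filter_order``), RMS-equalized
    to ``target_rms``, jointly rescaled if needed so no sample exceeds 1 in
    magnitude (the same factor for A and B, preserving RMS equality), and
    finally ramped. Ramping last slightly lowers the realized RMS, by an
    identical factor for A and B.

    The master ``seed`` deterministically yields two sub-streams, one for the
    noise draw and one for the permutation.
    """
    low, high = band
    if not (0 < low < high < rate / 2):
        raise ValueError(f"band {band} must satisfy 0 < low < high < Nyquist")
    n = int(round(duration * rate))
    a_raw, b_raw = raw_noise_pair(seed, n)

    sos = signal.butter(filter_order, band, btype="bandpass", fs=rate, output="sos")
    a_f, b_f = signal.sosfiltfilt(sos, a_raw), signal.sosfiltfilt(sos, b_raw)

    a_w = StimulusWaveform(a_f, rate, "A")
    b_w = StimulusWaveform(b_f, rate, "B")
    a_w, b_w = rms_normalize([a_w, b_w], target_rms=target_rms)

    env = _linear_ramp_envelope(n, rate, ramp)
    a_w = replace(a_w, samples=a_w.samples * env)
    b_w = replace(b_w, samples=b_w.samples * env)
    # ramping weights different samples in A and B, so re-equalize the realized
    # RMS exactly (scale-only; envelope time course untouched)
    target = 0.5 * (a_w.rms + b_w.rms)
    a_w, b_w = rms_normalize([a_w, b_w], target_rms=target)

    peak = max(np.max(np.abs(a_w.samples)), np.max(np.abs(b_w.samples)))
    if peak > 1.0:
        a_w = replace(a_w, samples=a_w.samples / peak)
        b_w = replace(b_w, samples=b_w.samples / peak)
    return a_w, b_w


def assemble_sequence(
    A: StimulusWaveform,
    B: StimulusWaveform,
    pattern: str = "AAAAB",
    base_rate: float = 8.0,
    n_loops: int = 64,
    gain: float = 1.0,
) -> OddballSequence:
    """Loop ``pattern`` (e.g. AAAAB) ``n_loops`` times at ``base_rate`` Hz.

    Each stimulus occupies exactly one 1/base_rate slot, zero-padded if it is
    shorter than the slot; a marker is emitted at every slot onset. With the
    defaults (AAAAB, 8 Hz, 64 loops) this yields a 40-s sequence whose deviant
    recurs at 8/5 = 1.6 Hz.

    ``gain`` scales the whole waveform; the frequency–intensity sequences are
    conventionally played at about half the amplitude of the noise sequences
    (``gain=0.5``) to match perceived intensity.
    """
    if A.rate != B.rate:
        raise ValueError("A and B must share a sample rate")
    if A.samples.size != B.samples.size:
        raise ValueError("A and B must share a duration")
    if not set(pattern) <= {"A", "B"}:
        raise ValueError("pattern may only contain labels 'A' and 'B'")
    rate = A.rate
    slot = rate / base_rate
    if abs(slot - round(slot)) > 1e-9:
        raise ValueError("sample rate must be an integer multiple of base_rate")
    slot = int(round(slot))
    if A.samples.size > slot:
        raise ValueError("stimulus longer than the 1/base_rate slot")

    stim = {"A": A.samples, "B": B.samples}
    pad = slot - A.samples.size
    one_loop = np.concatenate(
        [np.concatenate([stim[c], np.zeros(pad)]) for c in pattern]
    )
    waveform = np.tile(one_loop, n_loops) * gain

    markers = [
        ((k * len(pattern) + i) * slot / rate, c)
        for k in range(n_loops)
        for i, c in enumerate(pattern)
    ]
    return OddballSequence(
        waveform=waveform,
        rate=rate,
        base_rate=base_rate,
        pattern=pattern,
        n_loops=n_loops,
        markers=markers,
    )


# ---------------------------------------------------------------------------
# file export


def write_wav(path, waveform: np.ndarray, rate: float) -> None:
    """Write a waveform as 32-bit float WAV."""
    wavfile.write(path, int(round(rate)), np.asarray(waveform, dtype=np.float32))


def write_waveform_tsv(path, waveform: np.ndarray, rate: float) -> None:
    """Write (time_s, amplitude) two-column TSV."""
    t = np.arange(len(waveform)) / rate
    np.savetxt(
        path,
        np.column_stack([t, waveform]),
        delimiter="\t",
        header="time_s\tamplitude",
        comments="",
    )


def write_markers_tsv(path, markers: list) -> None:
    """Write sequence markers as an (onset_s, label) TSV table."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["onset_s", "label"])
        for onset, label in markers:
            w.writerow([f"{onset:.9g}", label])
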