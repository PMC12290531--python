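"""Synthetic multichannel EEG with ground-truth frequency-tagged sources.

Emulates the statistical structure the analysis chain assumes: 40-s trials
containing sinusoidal components strictly phase-locked across trials at the
base-rate (8 Hz) and oddball-rate (1.6 Hz) harmonics, projected onto
site-specific scalp topographies — a left-lateralized central bump for the
hand, a midline central bump for the foot — and buried in fresh 1/f-plus-
white noise per trial and channel. A dataset mirrors the study design:
17 subjects x 2 stimulation sites x 2 conditions x 8 trials, with
log-normal between-subject amplitude jitter and a ground-truth table of the
realized per-harmonic amplitudes.

Defaults place the channel-averaged aggregated responses in the
10^-3–10^-2 µV range after baseline subtraction, the order of magnitude a
64-channel scalp recording of these responses yields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .freqtag import build_harmonic_sets
from .montage import standard_64_montage
from .preprocess import EEGRecording, EpochSet

__all__ = [
    "SourceSpec",
    "NoiseSpec",
    "make_topography",
    "default_source",
    "simulate_subject",
    "simulate_dataset",
    "SimulatedDataset",
]

#: spatial spread (m) of the synthetic scalp bumps
TOPO_WIDTH = 0.035
#: amplitude of the strongest base harmonic, µV (source space)
BASE_AMP0 = 0.35
#: spectral decay constant (Hz) of the harmonic amplitude profile
AMP_DECAY_HZ = 30.0
#: oddball harmonics carry this fraction of the base profile
ODDBALL_FRACTION = 0.3


@dataclass(frozen=True)
class SourceSpec:
    """One phase-locked tagged source: topography + per-harmonic amplitudes."""

    site: str
    topography: np.ndarray  # per-channel gain, unit norm
    base_freqs: np.ndarray
    base_amplitudes: np.ndarray  # µV, aligned with base_freqs
    oddball_freqs: np.ndarray
    oddball_amplitudes: np.ndarray  # µV, aligned with oddball_freqs
    phases_base: np.ndarray | None = None  # radians; defaults to 0
    phases_oddball: np.ndarray | None = None


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: 1/f^alpha pink plus white, per trial and channel.

    ``pink_scale`` and ``white_scale`` are RMS contributions in µV of each
    component over the epoch; ``pink_exponent`` is the power-spectral slope.
    The defaults model the stationary background residue that survives
    preprocessing, ocular cleanup, artifact rejection and within-cell trial
    structure — not raw resting-scalp EEG (tens of µV RMS). They are
    deliberately placed in the near-asymptotic regime of the quantification
    chain: because responses are measured as spectral *magnitudes*, noise of
    the same order as the per-channel signal induces a systematic (Rician)
    downward bias at response bins after baseline subtraction, a property of
    the method itself. Ground-truth validation of the chain requires the
    regime where that bias is negligible; raise the scales to study the
    biased regime explicitly.
    """

    pink_exponent: float = 1.0
    pink_scale: float = 0.1
    white_scale: float = 0.05

    def __post_init__(self) -> None:
        if self.pink_exponent < 0 or self.pink_scale < 0 or self.white_scale < 0:
            raise ValueError("noise parameters must be nonnegative")


def make_topography(
    site: str,
    montage: np.ndarray,
    ch_names: list,
    width: float = TOPO_WIDTH,
    floor: float = 0.15,
) -> np.ndarray:
    """Unit-norm, compactly supported Gaussian scalp bump for a site.

    hand: centered between C3 and C1 (left-central, contralateral to right-
    hand stimulation); foot: centered between Cz and CPz (midline central).
    Gains below ``floor`` times the peak are zeroed so that every active
    electrode carries signal well above the simulation noise floor — the
    diffuse far tail of a pure Gaussian would otherwise hold ground-truth
    channel averages hostage to electrodes with unresolvable signal.
    """
    idx = {c: i for i, c in enumerate(ch_names)}
    if site == "hand":
        anchors = ("C3", "C1")
    elif site == "foot":
        anchors = ("Cz", "CPz")
    else:
        raise ValueError(f"unknown site {site!r}")
    center = np.mean([montage[idx[a]] for a in anchors], axis=0)
    d2 = np.sum((montage - center) ** 2, axis=1)
    g = np.exp(-d2 / (2 * width**2))
    g[g < floor * g.max()] = 0.0
    return g / np.linalg.norm(g)


def _default_amplitude(freqs: np.ndarray, a0: float) -> np.ndarray:
    return a0 * np.exp(-np.asarray(freqs) / AMP_DECAY_HZ)


def default_source(
    site: str,
    montage: np.ndarray,
    ch_names: list,
    f_base: float = 8.0,
    f_odd: float = 1.6,
    fmax: float = 40.0,
    base_amp0: float = BASE_AMP0,
    oddball_fraction: float = ODDBALL_FRACTION,
    topography: np.ndarray | None = None,
) -> SourceSpec:
    """Source with the default exponentially tapering harmonic profile."""
    base, odd = build_harmonic_sets(f_base, f_odd, fmax, bin_width=f_odd / 64)
    topo = (
        topography
        if topography is not None
        else make_topography(site, montage, ch_names)
    )
    return SourceSpec(
        site=site,
        topography=topo,
        base_freqs=base.frequencies,
        base_amplitudes=_default_amplitude(base.frequencies, base_amp0),
        oddball_freqs=odd.frequencies,
        oddball_amplitudes=_default_amplitude(
            odd.frequencies, oddball_fraction * base_amp0
        ),
    )


def _noise_trials(
    noise: NoiseSpec, shape: tuple, n: int, rate: float, rng, dtype
) -> np.ndarray:
    """Frequency-domain synthesis of pink + white noise, shape + (n,).

    Pink and white components are independent Gaussian processes, so a
    single complex draw against the root-sum-square magnitude profile
    realizes their sum. With unit-variance complex coefficients z the
    per-sample variance is 4*sum(mag^2)/n^2; each component's magnitudes are
    scaled so its time-domain RMS equals its ``*_scale``.
    """
    rows = int(np.prod(shape))
    nb = n // 2 + 1
    if noise.pink_scale == 0 and noise.white_scale == 0:
        return np.zeros((*shape, n), dtype=dtype)
    mag2 = np.zeros(nb, dtype=dtype)
    if noise.pink_scale > 0:
        f = np.arange(1, nb, dtype=dtype)
        p = f ** (-noise.pink_exponent)
        mag2[1:] += p * (noise.pink_scale * n / 2.0) ** 2 / np.sum(p)
    if noise.white_scale > 0:
        mag2[1:] += (noise.white_scale * n / 2.0) ** 2 / (nb - 1)
    mag = np.sqrt(mag2)
    z = rng.standard_normal((rows, 2 * nb), dtype=dtype).view(
        np.complex64 if dtype == np.float32 else np.complex128
    )
    out = np.fft.irfft(z * mag, n=n, axis=1).astype(dtype, copy=False)
    return out.reshape(*shape, n)


def _signal_trial(
    sources: list[SourceSpec], n: int, rate: float, dtype
) -> np.ndarray:
    """Deterministic phase-locked component, (n_channels, n)."""
    t = np.arange(n) / rate
    n_ch = sources[0].topography.size
    sig = np.zeros((n_ch, n))
    for src in sources:
        for freqs, amps, phases in (
            (src.base_freqs, src.base_amplitudes, src.phases_base),
            (src.oddball_freqs, src.oddball_amplitudes, src.phases_oddball),
        ):
            ph = np.zeros(len(freqs)) if phases is None else np.asarray(phases)
            for f, a, p in zip(freqs, amps, ph):
                k = f * n / rate
                if abs(k - round(k)) > 1e-9:
                    raise ValueError(f"harmonic {f} Hz misaligned for n={n}, rate={rate}")
                sig += (a * np.cos(2 * np.pi * f * t + p))[None, :] * src.topography[:, None]
    return sig.astype(dtype)


def simulate_trials(
    sources: list[SourceSpec],
    noise: NoiseSpec,
    n_trials: int = 8,
    duration: float = 40.0,
    rate: float = 2000.0,
    rng=None,
    dtype=np.float64,
) -> np.ndarray:
    """(n_trials, n_channels, n_samples) array: locked signal + fresh noise."""
    rng = np.random.default_rng(rng)
    n = int(round(duration * rate))
    n_ch = sources[0].topography.size if sources else 1
    sig = (
        _signal_trial(sources, n, rate, dtype)
        if sources
        else np.zeros((n_ch, n), dtype=dtype)
    )
    trials = _noise_trials(noise, (n_trials, n_ch), n, rate, rng, dtype)
    trials += sig[None]
    return trials


def simulate_subject(
    sources: list[SourceSpec],
    noise: NoiseSpec,
    n_trials: int = 8,
    duration: float = 40.0,
    rate: float = 2000.0,
    ch_names: list | None = None,
    montage: np.ndarray | None = None,
    seed=None,
    dtype=np.float64,
) -> EEGRecording:
    """Continuous recording of back-to-back trials with onset triggers."""
    trials = simulate_trials(sources, noise, n_trials, duration, rate, seed, dtype)
    n_trials_, n_ch, n = trials.shape
    data = trials.transpose(1, 0, 2).reshape(n_ch, n_trials_ * n)
    events = [(k * n, "trial") for k in range(n_trials_)]
    if ch_names is None:
        ch_names = [f"ch{i}" for i in range(n_ch)]
    return EEGRecording(
        data=data.astype(float),
        rate=rate,
        ch_names=ch_names,
        montage=montage,
        events=events,
    )


@dataclass
class SimulatedDataset:
    """Lazily generated study-design dataset with a ground-truth table.

    ``iter_cells()`` yields one :class:`EpochSet` per (subject, site,
    condition) cell, fully reproducible from the master seed; the
    ``ground_truth`` frame lists every injected harmonic amplitude (source
    scale and channel-averaged scale) per cell and response kind.
    """

    n_subjects: int
    sites: tuple
    conditions: tuple
    n_trials: int
    duration: float
    rate: float
    noise: NoiseSpec
    ch_names: list
    montage: np.ndarray
    topographies: dict
    sources_mean: dict  # site -> SourceSpec at condition means
    jitter: np.ndarray  # (subj, site, cond, kind) multiplicative factors
    detect_prob: dict
    seed: int
    dtype: type = np.float64
    ground_truth: pd.DataFrame = field(default=None, repr=False)

    def _cell_source(self, subj: int, i_site: int, i_cond: int) -> SourceSpec:
        site = self.sites[i_site]
        src = self.sources_mean[site]
        jb = self.jitter[subj, i_site, i_cond, 0]
        jo = self.jitter[subj, i_site, i_cond, 1]
        return SourceSpec(
            site=site,
            topography=src.topography,
            base_freqs=src.base_freqs,
            base_amplitudes=src.base_amplitudes * jb,
            oddball_freqs=src.oddball_freqs,
            oddball_amplitudes=src.oddball_amplitudes * jo,
        )

    def iter_cells(self):
        ss = np.random.SeedSequence(self.seed)
        keys = [
            (s, i, j)
            for s in range(self.n_subjects)
            for i in range(len(self.sites))
            for j in range(len(self.conditions))
        ]
        n = int(round(self.duration * self.rate))
        t = np.arange(n) / self.rate
        # per-site unit-jitter waveforms; a cell's signal is a scaled outer
        # product with the site topography
        waves = {}
        for site in self.sites:
            src = self.sources_mean[site]
            bw = np.zeros(n)
            for f, a in zip(src.base_freqs, src.base_amplitudes):
                bw += a * np.cos(2 * np.pi * f * t)
            ow = np.zeros(n)
            for f, a in zip(src.oddball_freqs, src.oddball_amplitudes):
                ow += a * np.cos(2 * np.pi * f * t)
            waves[site] = (bw.astype(self.dtype), ow.astype(self.dtype))
        for (s, i, j), child in zip(keys, ss.spawn(len(keys))):
            rng = np.random.default_rng(child)
            site = self.sites[i]
            bw, ow = waves[site]
            jb = self.dtype(self.jitter[s, i, j, 0])
            jo = self.dtype(self.jitter[s, i, j, 1])
            topo = self.sources_mean[site].topography.astype(self.dtype)
            n_ch = topo.size
            trials = _noise_trials(
                self.noise, (self.n_trials, n_ch), n, self.rate, rng, self.dtype
            )
            trials += topo[None, :, None] * (jb * bw + jo * ow)[None, None, :]
            cond = self.conditions[j]
            detected = rng.random(self.n_trials) < self.detect_prob.get(cond, 0.5)
            meta = pd.DataFrame(
                {
                    "subject": s,
                    "site": self.sites[i],
                    "condition": cond,
                    "sequence_id": np.arange(self.n_trials),
                    "detected": detected,
                }
            )
            yield EpochSet(
                data=trials.astype(float),
                rate=self.rate,
                ch_names=list(self.ch_names),
                montage=self.montage,
                window=(0.0, self.duration),
                meta=meta,
            )

    @property
    def n_trials_total(self) -> int:
        return self.n_subjects * len(self.sites) * len(self.conditions) * self.n_trials


def simulate_dataset(
    n_subjects: int = 17,
    sites: tuple = ("hand", "foot"),
    conditions: tuple = ("frequency_intensity", "spectrotemporal"),
    n_trials: int = 8,
    duration: float = 40.0,
    rate: float = 2000.0,
    noise: NoiseSpec | None = None,
    between_subject_sd: float = 0.3,
    seed: int = 0,
    montage: tuple | None = None,
    distinct_topographies: bool = True,
    detect_prob: dict | None = None,
    dtype=np.float64,
    base_amp0: float = BASE_AMP0,
    oddball_fraction: float = ODDBALL_FRACTION,
) -> SimulatedDataset:
    """Build the full study-design simulation (lazily realized).

    ``between_subject_sd`` is the sigma of the multiplicative log-normal
    amplitude jitter, drawn independently per (subject, site, condition,
    response kind). ``distinct_topographies=False`` gives both sites the hand
    topography — the no-somatotopy null in which the site x template
    interaction holds at its nominal level. ``detect_prob`` sets per-
    condition trial detection probabilities (defaults 0.7 for the
    frequency–intensity and 0.375 for the spectrotemporal contrast, the
    behavioral rates such experiments report).
    """
    if montage is None:
        ch_names, coords = standard_64_montage()
    else:
        ch_names, coords = montage
    noise = NoiseSpec() if noise is None else noise
    detect_prob = detect_prob or {"frequency_intensity": 0.7, "spectrotemporal": 0.375}

    topo = {
        "hand": make_topography("hand", coords, ch_names),
        "foot": make_topography("foot", coords, ch_names),
    }
    if not distinct_topographies:
        topo = {s: topo["hand"] for s in sites}
    sources_mean = {
        s: default_source(
            s, coords, ch_names,
            base_amp0=base_amp0, oddball_fraction=oddball_fraction,
            topography=topo[s],
        )
        for s in sites
    }

    ss = np.random.SeedSequence([seed, 0x5EED])
    rng = np.random.default_rng(ss)
    jitter = np.exp(
        between_subject_sd
        * rng.standard_normal((n_subjects, len(sites), len(conditions), 2))
    )

    ds = SimulatedDataset(
        n_subjects=n_subjects,
        sites=tuple(sites),
        conditions=tuple(conditions),
        n_trials=n_trials,
        duration=duration,
        rate=rate,
        noise=noise,
        ch_names=ch_names,
        montage=coords,
        topographies=topo,
        sources_mean=sources_mean,
        jitter=jitter,
        detect_prob=detect_prob,
        seed=seed,
        dtype=dtype,
    )

    rows = []
    for s in range(n_subjects):
        for i, site in enumerate(sites):
            src = sources_mean[site]
            topo_mean = float(src.topography.mean())
            for j, cond in enumerate(conditions):
                for kind, freqs, amps, k in (
                    ("base", src.base_freqs, src.base_amplitudes, 0),
                    ("oddball", src.oddball_freqs, src.oddball_amplitudes, 1),
                ):
                    for f, a in zip(freqs, amps):
                        a_real = a * jitter[s, i, j, k]
                        rows.append(
                            {
                                "subject": s,
                                "site": site,
                                "condition": cond,
                                "kind": kind,
                                "harmonic_hz": f,
                                "amplitude_uV": a_real,
                                "channel_mean_uV": a_real * topo_mean,
                            }
                        )
    ds.ground_truth = pd.DataFrame(rows)
    return ds
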