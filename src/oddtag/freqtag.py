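"""Frequency-domain quantification of base and oddball responses.

With an AAAAB train at an 8 Hz base rate, activity common to standards and
deviants projects at 8 Hz and harmonics, while discrimination of the deviant
projects at 1.6 Hz (= 8/5) and its harmonics. Per condition, trials are
averaged in the time domain (phase-locked activity survives, background EEG
cancels), a 40-s epoch FFT gives 0.025 Hz amplitude resolution, and a local
baseline — the mean of the 24 neighboring bins, 12 per side with the two
immediately adjacent bins excluded — is subtracted at every bin so that, in
the absence of a tagged response, amplitudes tend to zero. Responses are then
aggregated as the mean baseline-subtracted amplitude over the harmonic set
(base: multiples of 8 Hz up to 40; oddball: multiples of 1.6 Hz up to 40,
excluding the base members) and tested against zero with right-tailed
one-sample t-tests across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import EpochSet

__all__ = [
    "AmplitudeSpectrum",
    "HarmonicSet",
    "ResponseTest",
    "MisalignedFrequencyError",
    "average_trials",
    "amplitude_spectrum",
    "baseline_subtract",
    "build_harmonic_sets",
    "aggregate_response",
    "test_response",
    "compare_detected_split",
    "relate_dissimilarity_response",
]


class MisalignedFrequencyError(ValueError):
    """An analysis frequency does not fall exactly on a spectrum bin."""


@dataclass
class AmplitudeSpectrum:
    """One-sided per-channel amplitude spectrum in µV.

    Scaling: a bin-aligned sinusoid of peak amplitude *a* yields exactly *a*
    at its bin (2|X_k|/N for interior bins, |X_k|/N at DC and Nyquist). Any
    fixed convention cancels in baseline subtraction and group statistics;
    this one makes injected amplitudes directly readable.
    """

    amplitudes: np.ndarray  # (n_channels, n_bins)
    bin_width: float
    stage: str = "raw"  # raw | baseline_subtracted
    ch_names: list | None = None

    def __post_init__(self) -> None:
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.amplitudes.shape[1]) * self.bin_width

    @property
    def n_bins(self) -> int:
        return self.amplitudes.shape[1]

    def bin_index(self, freq: float, tol: float = 1e-9) -> int:
        """Index of the bin at ``freq``; raises if misaligned."""
        k = freq / self.bin_width
        if abs(k - round(k)) > tol:
            raise MisalignedFrequencyError(
                f"{freq} Hz is not a multiple of the {self.bin_width} Hz bin width"
            )
        k = int(round(k))
        if not 0 <= k < self.n_bins:
            raise MisalignedFrequencyError(f"{freq} Hz outside the spectrum")
        return k


@dataclass(frozen=True)
class HarmonicSet:
    """Harmonics of a fundamental up to a cutoff, optionally minus exclusions."""

    kind: str  # base | oddball
    fundamental: float
    fmax: float
    frequencies: np.ndarray = field(default_factory=lambda: np.empty(0))


class ResponseTest(NamedTuple):
    t: float
    p: float
    mean: float
    sd: float
    n: int
    degenerate: bool


def average_trials(ep: EpochSet, by=("site", "condition")) -> dict:
    """Arithmetic mean across trials within each metadata group.

    Returns ``{group_key: (n_channels, n_samples) array}``; with ``by=None``
    a single key ``"all"`` averages every trial. An extra ``"detected"`` key
    in ``by`` supports the detected/non-detected split.
    """
    if ep.n_trials == 0:
        raise ValueError("no trials to average")
    if by is None:
        return {"all": ep.data.mean(axis=0)}
    by = [k for k in by if k in ep.meta.columns]
    if not by:
        return {"all": ep.data.mean(axis=0)}
    out = {}
    for key, grp in ep.meta.groupby(list(by), sort=True, dropna=False):
        key = key if len(by) > 1 else key[0]
        out[key] = ep.data[grp.index.to_numpy()].mean(axis=0)
    return out


def amplitude_spectrum(
    avg: np.ndarray, rate: float, require_aligned=()
) -> AmplitudeSpectrum:
    """One-sided amplitude spectrum of a (channels x samples) average.

    ``bin_width = 1/duration`` (0.025 Hz for a 40-s epoch). Frequencies in
    ``require_aligned`` must land exactly on bins, otherwise a
    :class:`MisalignedFrequencyError` is raised (e.g. 1.6 Hz on a 40-s epoch:
    1.6 / 0.025 = 64, exact).
    """
    avg = np.atleast_2d(np.asarray(avg, dtype=float))
    n = avg.shape[1]
    bin_width = rate / n
    for f in require_aligned:
        k = f / bin_width
        if abs(k - round(k)) > 1e-9:
            raise MisalignedFrequencyError(
                f"{f} Hz misaligned with the {bin_width} Hz bin grid"
            )
    amp = np.abs(np.fft.rfft(avg, axis=1)) / n
    amp[:, 1:] *= 2.0
    if n % 2 == 0:  # un-double the unpaired Nyquist bin
        amp[:, -1] /= 2.0
    return AmplitudeSpectrum(amplitudes=amp, bin_width=bin_width, stage="raw")


def baseline_subtract(
    spec: AmplitudeSpectrum, half_width: int = 13, gap: int = 1
) -> AmplitudeSpectrum:
    """Subtract the mean of the flanking bins at every frequency bin.

    At bin *k* the baseline is the mean over offsets ±(gap+1) .. ±half_width
    — with the defaults, 12 bins per side (24 total), excluding the bins
    immediately adjacent to *k*. Near the spectrum edges the window truncates
    to the offsets that exist. This cancels locally smooth broadband
    background, leaving narrow-band tagged responses.
    """
    if spec.n_bins < 2 * half_width + 1:
        raise ValueError("spectrum too short for the baseline window")
    offs = np.r_[-half_width : -gap, gap + 1 : half_width + 1]
    amp = spec.amplitudes
    n = spec.n_bins
    total = np.zeros_like(amp)
    count = np.zeros(n)
    for o in offs:
        lo, hi = max(0, -o), min(n, n - o)
        total[:, lo:hi] += amp[:, lo + o : hi + o]
        count[lo:hi] += 1
    return replace(spec, amplitudes=amp - total / count, stage="baseline_subtracted")


def build_harmonic_sets(
    f_base: float = 8.0,
    f_odd: float = 1.6,
    fmax: float = 40.0,
    bin_width: float = 0.025,
) -> tuple[HarmonicSet, HarmonicSet]:
    """Base and oddball harmonic sets up to ``fmax``.

    Base: all multiples of ``f_base`` up to ``fmax`` (defaults: 8, 16, 24,
    32, 40 Hz). Oddball: multiples of ``f_odd`` up to ``fmax`` minus the base
    members (defaults: 20 frequencies). ``f_base`` must be an integer
    multiple of ``f_odd`` and every harmonic must sit on the bin grid.
    """
    ratio = f_base / f_odd
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("f_base must be an integer multiple of f_odd")
    ratio = int(round(ratio))
    tol = 1e-9

    def bins(f0):
        ks = np.arange(1, int(np.floor(fmax / f0 + tol)) + 1)
        freqs = ks * f0
        for f in freqs:
            b = f / bin_width
            if abs(b - round(b)) > tol:
                raise MisalignedFrequencyError(
                    f"harmonic {f} Hz misaligned with bin width {bin_width} Hz"
                )
        return ks, freqs

    _, base_freqs = bins(f_base)
    odd_ks, odd_freqs = bins(f_odd)
    odd_freqs = odd_freqs[odd_ks % ratio != 0]  # every ratio-th is a base harmonic
    return (
        HarmonicSet("base", f_base, fmax, base_freqs),
        HarmonicSet("oddball", f_odd, fmax, odd_freqs),
    )


def aggregate_response(
    spec_bs: AmplitudeSpectrum, hset: HarmonicSet, scope: str = "channel_mean"
):
    """Mean baseline-subtracted amplitude over the harmonic-set bins.

    ``scope='channel_mean'`` averages over channels first (group statistics);
    ``scope='per_channel'`` keeps the per-channel vector (topographies and
    the somatotopy test).
    """
    if spec_bs.stage != "baseline_subtracted":
        raise ValueError("aggregate_response requires a baseline-subtracted spectrum")
    idx = [spec_bs.bin_index(f) for f in hset.frequencies]
    vals = spec_bs.amplitudes[:, idx].mean(axis=1)
    if scope == "per_channel":
        return vals
    if scope == "channel_mean":
        return float(vals.mean())
    raise ValueError("scope must be 'per_channel' or 'channel_mean'")


def _one_sample_t(values, alternative: str) -> ResponseTest:
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 values")
    m, sd = float(v.mean()), float(v.std(ddof=1))
    if sd == 0.0:
        # degenerate zero-variance contract: direction decides the p limit
        t = np.inf * np.sign(m) if m != 0 else 0.0
        if alternative == "greater":
            p = 0.0 if m > 0 else (0.5 if m == 0 else 1.0)
        else:
            p = 1.0 if m == 0 else 0.0
        return ResponseTest(float(t), p, m, sd, n, degenerate=True)
    res = stats.ttest_1samp(v, 0.0, alternative=alternative)
    return ResponseTest(float(res.statistic), float(res.pvalue), m, sd, n, False)


def test_response(values) -> ResponseTest:
    """Right-tailed one-sample t-test of per-subject aggregates against zero.

    Zero-variance input follows an explicit degenerate contract: t = ±inf,
    p -> 0 for a positive mean, and the result is flagged.
    """
    return _one_sample_t(values, "greater")


def compare_detected_split(pairs) -> ResponseTest:
    """Two-sided paired t-test on per-subject (detected, non-detected) pairs.

    Only subjects contributing both categories enter; the test is run on the
    per-subject differences.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (n_subjects, 2)")
    return _one_sample_t(arr[:, 0] - arr[:, 1], "two-sided")


def relate_dissimilarity_response(D, R) -> tuple[float, float]:
    """Spearman rank correlation between per-sequence envelope dissimilarity
    and per-sequence oddball response, with two-sided p."""
    D, R = np.asarray(D, float), np.asarray(R, float)
    if D.size != R.size or D.size < 3:
        raise ValueError("need >= 3 paired sequences")
    if np.ptp(D) == 0 or np.ptp(R) == 0:
        raise ValueError("constant input vector")
    rho, p = stats.spearmanr(D, R)
    return float(rho), float(p)


def response_table(rows) -> pd.DataFrame:
    """Assemble (subject, site, condition, kind, channel, value_uV) rows."""
    return pd.DataFrame(
        rows, columns=["subject", "site", "condition", "kind", "channel", "value_uV"]
    )
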