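"""Continuous-EEG cleaning and epoching.

The cleaning chain applied before spectral analysis, in fixed order:

1. DC removal + linear detrend (per channel, continuous record);
2. zero-phase Butterworth band-pass, 0.1–40 Hz, design order 4;
3. downsampling, 2000 Hz -> 500 Hz by default;
4. interpolation of visually identified bad channels (mean of the three
   nearest good electrodes by 3-D montage distance);
5. segmentation into [0, 40) s epochs at the trial triggers;
6. automatic rejection of trials exceeding a 500 µV amplitude criterion;
7. re-referencing to the average of all scalp channels.

Ocular-artifact ICA is deliberately not part of this chain — component
selection is a manual, visual step — so the entry points accept either raw
or externally cleaned continuous data. All data are held in µV.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "EEGRecording",
    "EpochSet",
    "detrend_dc",
    "bandpass_filter",
    "resample",
    "epoch_trials",
    "interpolate_bad_channels",
    "reject_artifact_trials",
    "rereference_average",
    "preprocess_pipeline",
    "read_edf",
    "read_matrix",
    "read_markers_tsv",
]


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in µV with trigger events.

    Attributes
    ----------
    data : (n_channels, n_samples) float array, µV
    rate : sample rate, samples/s
    ch_names : unique channel labels
    montage : (n_channels, 3) electrode positions, or None
    events : list of (sample_index, code) trigger pairs
    """

    data: np.ndarray
    rate: float
    ch_names: list
    montage: np.ndarray | None = None
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("channel label count does not match data rows")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if self.montage is not None:
            self.montage = np.asarray(self.montage, dtype=float)
            if self.montage.shape != (self.data.shape[0], 3):
                raise ValueError("montage must be (n_channels, 3) covering all channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Trial-segmented EEG: (n_trials, n_channels, n_samples) in µV.

    ``meta`` carries one row per trial (site, condition, sequence_id,
    detected, ...); the epoch window is [0, 40) s relative to the trigger by
    default, so every epoch holds exactly ``40 * rate`` samples.
    """

    data: np.ndarray
    rate: float
    ch_names: list
    montage: np.ndarray | None = None
    window: tuple = (0.0, 40.0)
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if self.window[0] != 0.0:
            raise ValueError("epoch window must start at the trigger (0 s)")
        if self.meta is None:
            self.meta = pd.DataFrame(index=range(self.data.shape[0]))
        if len(self.meta) != self.data.shape[0]:
            raise ValueError("meta must have one row per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def save(self, path) -> None:
        """Round-trip persistable store (portable .npz container)."""
        np.savez_compressed(
            path,
            data=self.data,
            rate=self.rate,
            ch_names=np.array(self.ch_names, dtype=object),
            montage=self.montage if self.montage is not None else np.empty((0, 3)),
            window=np.array(self.window),
            meta_json=np.array(self.meta.to_json(orient="table")),
        )

    @classmethod
    def load(cls, path) -> "EpochSet":
        z = np.load(path, allow_pickle=True)
        montage = z["montage"]
        meta = pd.read_json(io.StringIO(str(z["meta_json"])), orient="table")
        return cls(
            data=z["data"],
            rate=float(z["rate"]),
            ch_names=list(z["ch_names"]),
            montage=None if montage.size == 0 else montage,
            window=tuple(z["window"]),
            meta=meta.reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# chain steps


def detrend_dc(rec: EEGRecording) -> EEGRecording:
    """Remove the per-channel best-fit line (DC offset + linear drift)."""
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples to detrend")
    return replace(rec, data=signal.detrend(rec.data, axis=1, type="linear"))


def bandpass_filter(
    rec: EEGRecording, low: float = 0.1, high: float = 40.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass of stated design order.

    Applied forward–backward (``sosfiltfilt``) to avoid phase distortion of
    the harmonic components on which trial averaging relies; the effective
    magnitude response is therefore the squared design response.
    """
    if not (0 < low < high < rec.rate / 2):
        raise ValueError(f"need 0 < {low} < {high} < Nyquist ({rec.rate / 2})")
    sos = signal.butter(order, (low, high), btype="bandpass", fs=rec.rate, output="sos")
    return replace(rec, data=signal.sosfiltfilt(sos, rec.data, axis=1))


def resample(rec: EEGRecording, new_rate: float = 500.0) -> EEGRecording:
    """Downsample with polyphase anti-aliased resampling; remap events.

    Only downsampling is supported; event sample indices move to the nearest
    sample of the new grid.
    """
    if new_rate >= rec.rate:
        raise ValueError("resample only supports downsampling")
    frac = Fraction(new_rate / rec.rate).limit_denominator(10000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    events = [
        (int(round(s * new_rate / rec.rate)), code) for s, code in rec.events
    ]
    return replace(rec, data=data, rate=new_rate, events=events)


def interpolate_bad_channels(rec: EEGRecording, bad: list) -> EEGRecording:
    """Replace each bad channel by the mean of its 3 nearest good channels.

    Distance is 3-D Euclidean in montage coordinates; the neighbor average is
    unweighted. All bad channels are replaced from the original good signals
    simultaneously.
    """
    if not bad:
        return rec
    if rec.montage is None:
        raise ValueError("montage required for channel interpolation")
    idx = {c: i for i, c in enumerate(rec.ch_names)}
    missing = [c for c in bad if c not in idx]
    if missing:
        raise ValueError(f"bad channels not in recording: {missing}")
    bad_i = [idx[c] for c in bad]
    good_i = [i for i in range(rec.n_channels) if i not in set(bad_i)]
    if len(good_i) < 3:
        raise ValueError("need at least 3 good channels to interpolate")
    data = rec.data.copy()
    for bi in bad_i:
        d = np.linalg.norm(rec.montage[good_i] - rec.montage[bi], axis=1)
        nearest = np.array(good_i)[np.argsort(d)[:3]]
        data[bi] = rec.data[nearest].mean(axis=0)
        logger.info(
            "interpolated %s from %s",
            rec.ch_names[bi],
            [rec.ch_names[j] for j in nearest],
        )
    return replace(rec, data=data)


def epoch_trials(
    rec: EEGRecording,
    window: tuple = (0.0, 40.0),
    meta: pd.DataFrame | None = None,
) -> EpochSet:
    """Segment [window[0], window[1]) s epochs at every trigger.

    Epochs are half-open slices of exactly ``(t1 - t0) * rate`` samples;
    triggers without room for a full window are dropped with a warning.
    ``meta`` (one row per event, in event order) is subset to kept trials.
    """
    t0, t1 = window
    if t0 != 0.0:
        raise ValueError("epoch window must start at the trigger (0 s)")
    n_win = int(round((t1 - t0) * rec.rate))
    trials, kept = [], []
    for k, (s, code) in enumerate(rec.events):
        if s + n_win > rec.n_samples:
            logger.warning("dropping trigger %d at sample %d: window truncated", k, s)
            continue
        trials.append(rec.data[:, s : s + n_win])
        kept.append(k)
    if meta is not None:
        meta = meta.iloc[kept].reset_index(drop=True)
    else:
        meta = pd.DataFrame({"code": [rec.events[k][1] for k in kept]})
    data = np.stack(trials) if trials else np.empty((0, rec.n_channels, n_win))
    return EpochSet(
        data=data,
        rate=rec.rate,
        ch_names=list(rec.ch_names),
        montage=rec.montage,
        window=window,
        meta=meta,
    )


def reject_artifact_trials(ep: EpochSet, criterion: float = 500.0) -> EpochSet:
    """Drop trials whose max |amplitude| over all channels exceeds ``criterion`` µV."""
    if criterion <= 0:
        raise ValueError("criterion must be positive")
    peak = np.max(np.abs(ep.data), axis=(1, 2)) if ep.n_trials else np.empty(0)
    keep = peak <= criterion
    n_rej = int((~keep).sum())
    if n_rej:
        logger.info("rejected %d/%d trials above %g µV", n_rej, ep.n_trials, criterion)
    return replace(ep, data=ep.data[keep], meta=ep.meta[keep].reset_index(drop=True))


def rereference_average(ep):
    """Re-reference to the average of all scalp channels (works on epochs or
    continuous recordings); the per-sample cross-channel mean becomes 0."""
    ch_axis = 1 if isinstance(ep, EpochSet) else 0
    if ep.data.shape[ch_axis] < 2:
        raise ValueError("need at least 2 channels to average-reference")
    return replace(ep, data=ep.data - ep.data.mean(axis=ch_axis, keepdims=True))


def preprocess_pipeline(
    rec: EEGRecording,
    bad_channels: list = (),
    low: float = 0.1,
    high: float = 40.0,
    order: int = 4,
    resample_to: float | None = 500.0,
    window: tuple = (0.0, 40.0),
    criterion: float = 500.0,
    meta: pd.DataFrame | None = None,
) -> EpochSet:
    """Run the full cleaning chain in its fixed order.

    detrend -> band-pass -> downsample -> interpolate bad channels
    (continuous; epoching is pure slicing, so this equals interpolating just
    after segmentation) -> epoch -> amplitude rejection -> average reference.
    Each step is logged.
    """
    logger.info("chain: detrend")
    rec = detrend_dc(rec)
    logger.info("chain: band-pass %g-%g Hz (order %d)", low, high, order)
    rec = bandpass_filter(rec, low, high, order)
    if resample_to is not None and resample_to < rec.rate:
        logger.info("chain: resample %g -> %g Hz", rec.rate, resample_to)
        rec = resample(rec, resample_to)
    if bad_channels:
        logger.info("chain: interpolate %s", list(bad_channels))
        rec = interpolate_bad_channels(rec, list(bad_channels))
    logger.info("chain: epoch %s s", window)
    ep = epoch_trials(rec, window, meta=meta)
    logger.info("chain: reject > %g µV", criterion)
    ep = reject_artifact_trials(ep, criterion)
    logger.info("chain: average reference")
    return rereference_average(ep)


# ---------------------------------------------------------------------------
# readers


def read_edf(path, montage: tuple | None = None) -> EEGRecording:
    """Read an EDF recording into µV, with annotations as events.

    ``montage`` may be (labels, coords); channels present in the recording
    are matched by label. EDF physical dimensions are honored by the reader
    (data arrive in volts and are converted to µV).
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    data = raw.get_data() * 1e6  # V -> µV
    events = []
    for ann in raw.annotations:
        events.append((int(round(ann["onset"] * raw.info["sfreq"])), str(ann["description"])))
    coords = None
    if montage is not None:
        labels, pos = montage
        lut = {l: p for l, p in zip(labels, pos)}
        coords = np.array([lut[c] for c in raw.ch_names])
    return EEGRecording(
        data=data,
        rate=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        montage=coords,
        events=events,
    )


def read_matrix(path, rate: float, markers=None, montage: tuple | None = None) -> EEGRecording:
    """Read a delimited numeric matrix (channels in columns, labeled header).

    ``markers``: optional path of a TSV with columns (onset_s|sample, code).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    ch_names = [str(c) for c in df.columns]
    data = df.to_numpy(dtype=float).T
    events = read_markers_tsv(markers, rate) if markers is not None else []
    coords = None
    if montage is not None:
        labels, pos = montage
        lut = {l: p for l, p in zip(labels, pos)}
        coords = np.array([lut[c] for c in ch_names])
    return EEGRecording(data=data, rate=rate, ch_names=ch_names, montage=coords, events=events)


def read_markers_tsv(path, rate: float) -> list:
    """Read an event table with either an ``onset_s`` or a ``sample`` column."""
    df = pd.read_csv(path, sep="\t")
    if "sample" in df.columns:
        samples = df["sample"].astype(int)
    elif "onset_s" in df.columns:
        samples = (df["onset_s"].astype(float) * rate).round().astype(int)
    else:
        raise ValueError("marker table needs an 'onset_s' or 'sample' column")
    code_col = "code" if "code" in df.columns else df.columns[-1]
    return list(zip(samples.tolist(), df[code_col].astype(str).tolist()))
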