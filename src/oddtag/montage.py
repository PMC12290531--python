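"""Electrode montages: the standard 64-channel 10/10 set and TSV I/O."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["STANDARD_64_LABELS", "standard_64_montage", "load_montage_tsv", "save_montage_tsv"]

#: 64 labels of the International 10/10 system as used by common 64-channel caps
STANDARD_64_LABELS = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]


def standard_64_montage() -> tuple[list[str], np.ndarray]:
    """Standard 10/10 64-channel montage as (labels, 64x3 positions in m).

    Head coordinates: +x toward the right ear, +y toward the nasion, +z up,
    so left-hemisphere channels (C3, ...) have x < 0 and midline channels
    (Cz, ...) have x near 0.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        try:
            m = mne.channels.make_standard_montage("colin27_1020")
        except ValueError:  # older MNE naming
            m = mne.channels.make_standard_montage("standard_1020")
    pos = m.get_positions()["ch_pos"]
    coords = np.array([pos[lab] for lab in STANDARD_64_LABELS], dtype=float)
    return list(STANDARD_64_LABELS), coords


def load_montage_tsv(path) -> tuple[list[str], np.ndarray]:
    """Read a (label, x, y, z) TSV montage table."""
    df = pd.read_csv(path, sep="\t")
    return df.iloc[:, 0].astype(str).tolist(), df.iloc[:, 1:4].to_numpy(dtype=float)


def save_montage_tsv(path, labels, coords) -> None:
    pd.DataFrame(
        {
            "label": labels,
            "x": np.asarray(coords)[:, 0],
            "y": np.asarray(coords)[:, 1],
            "z": np.asarray(coords)[:, 2],
        }
    ).to_csv(path, sep="\t", index=False)
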