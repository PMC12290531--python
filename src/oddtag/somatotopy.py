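"""Weighted-channel-template test of scalp somatotopy.

The topography of the base response to a frequency–intensity localizer
condition is condensed, per stimulation site (hand, foot), into a
nonnegative per-channel weight vector summing to 1: harmonics of the base
rate whose channel-averaged amplitude is significantly above zero across
subjects are kept, the grand-average per-channel amplitude over those
harmonics is clipped at zero and normalized. Test-condition responses are
then weighted by the matched and the mismatched template and averaged over
channels, giving a 2 (stimulation site) x 2 (channel template) table per
subject. Somatotopy predicts a site x template interaction in a
repeated-measures ANOVA — hand responses score higher under the hand
template, foot responses under the foot template — probed by directional
paired post-hoc t-tests with Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .freqtag import AmplitudeSpectrum, HarmonicSet, ResponseTest, test_response

__all__ = [
    "ChannelTemplate",
    "EffectStats",
    "SomatotopyStats",
    "build_template",
    "weight_response",
    "rm_anova_2x2",
    "posthoc_paired",
    "somatotopy_test",
    "top_channels",
]


@dataclass(frozen=True)
class ChannelTemplate:
    """Nonnegative per-channel weights summing to 1 for one source site."""

    weights: np.ndarray
    source_site: str
    source_harmonics: np.ndarray
    ch_names: list | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("template weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("template weights must sum to 1")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class EffectStats:
    F: float
    p: float
    df: tuple
    eta2: float  # SS_effect / SS_total
    partial_eta2: float  # SS_effect / (SS_effect + SS_error)


@dataclass(frozen=True)
class SomatotopyStats:
    site: EffectStats
    template: EffectStats
    interaction: EffectStats
    posthoc: dict | None = None  # site -> (t, p, d, degenerate)


class NoSignificantHarmonicError(ValueError):
    def __init__(self, table: pd.DataFrame):
        self.table = table
        super().__init__(
            "no base harmonic significantly above zero; diagnostic table attached:\n"
            + table.to_string(index=False)
        )


def build_template(
    localizer: list[AmplitudeSpectrum] | np.ndarray,
    hset: HarmonicSet,
    source_site: str,
    alpha: float = 0.05,
    ch_names: list | None = None,
) -> ChannelTemplate:
    """Build a site template from per-subject baseline-subtracted spectra.

    Steps: (1) per harmonic, right-tailed one-sample t across subjects on the
    channel-averaged amplitude; keep harmonics with p < alpha (uncorrected);
    (2) grand-average the per-channel amplitudes across subjects and kept
    harmonics; (3) clip negatives to 0; (4) normalize to unit sum.

    ``localizer`` is a list of spectra (one per subject) or an
    (n_subjects, n_channels, n_bins) array with a known bin width taken from
    ``hset`` alignment — pass spectra for safety.
    """
    if isinstance(localizer, np.ndarray):
        raise TypeError("pass a list of AmplitudeSpectrum (one per subject)")
    if len(localizer) < 2:
        raise ValueError("need at least 2 subjects")
    for s in localizer:
        if s.stage != "baseline_subtracted":
            raise ValueError("templates are built from baseline-subtracted spectra")
    bins = [localizer[0].bin_index(f) for f in hset.frequencies]
    # n_subjects x n_channels x n_harmonics
    cube = np.stack([s.amplitudes[:, bins] for s in localizer])
    chan_avg = cube.mean(axis=1)  # subjects x harmonics

    rows, kept = [], []
    for j, f in enumerate(hset.frequencies):
        r = test_response(chan_avg[:, j])
        rows.append({"harmonic_hz": f, "t": r.t, "p": r.p, "mean_uV": r.mean})
        if r.p < alpha:
            kept.append(j)
    diag = pd.DataFrame(rows)
    if not kept:
        raise NoSignificantHarmonicError(diag)

    tpl = cube[:, :, kept].mean(axis=(0, 2))  # grand-average per channel
    tpl = np.clip(tpl, 0.0, None)
    if tpl.sum() == 0:
        raise NoSignificantHarmonicError(diag)
    return ChannelTemplate(
        weights=tpl / tpl.sum(),
        source_site=source_site,
        source_harmonics=hset.frequencies[kept],
        ch_names=ch_names,
    )


def weight_response(resp: np.ndarray, tpl: ChannelTemplate) -> float:
    """Template-weighted, channel-averaged response:
    value = (1/N) * sum_c resp_c * w_c."""
    resp = np.asarray(resp, dtype=float)
    if resp.shape != tpl.weights.shape:
        raise ValueError("response and template channel sets differ")
    return float(np.mean(resp * tpl.weights))


def _effect_from_contrast(per_subject: np.ndarray, ss_effect: float, ss_error: float,
                          ss_total: float) -> EffectStats:
    n = per_subject.size
    df = (1, n - 1)
    mse = ss_error / df[1]
    F = ss_effect / mse if mse > 0 else (np.inf if ss_effect > 0 else 0.0)
    p = float(stats.f.sf(F, *df)) if np.isfinite(F) else 0.0
    return EffectStats(
        F=float(F),
        p=p,
        df=df,
        eta2=float(ss_effect / ss_total) if ss_total > 0 else 0.0,
        partial_eta2=float(ss_effect / (ss_effect + ss_error))
        if (ss_effect + ss_error) > 0
        else 0.0,
    )


def rm_anova_2x2(table) -> SomatotopyStats:
    """2x2 fully within-subject ANOVA (site x template).

    ``table``: an (n_subjects, 2, 2) array ordered [site][template] with
    site axis (hand, foot) and template axis (hand, foot), or a long
    DataFrame with columns subject, site, template, value.

    Each effect has (1, n-1) degrees of freedom, and every F equals the
    squared paired t of the corresponding per-subject contrast — in
    particular the interaction F equals the squared paired t on the double
    differences (x_hh - x_hf) - (x_fh - x_ff). Both raw and partial eta
    squared are reported.
    """
    y = _as_cube(table)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    g = y.mean()
    subj = y.mean(axis=(1, 2))
    site_m = y.mean(axis=(0, 2))
    tpl_m = y.mean(axis=(0, 1))
    cell = y.mean(axis=0)

    ss_total = float(((y - g) ** 2).sum())
    ss_site = float(2 * n * ((site_m - g) ** 2).sum())
    ss_tpl = float(2 * n * ((tpl_m - g) ** 2).sum())
    ss_int = float(n * ((cell - site_m[:, None] - tpl_m[None, :] + g) ** 2).sum())
    sa = y.mean(axis=2)  # subject x site
    sb = y.mean(axis=1)  # subject x template
    ss_sa = float(2 * ((sa - site_m[None, :] - subj[:, None] + g) ** 2).sum())
    ss_sb = float(2 * ((sb - tpl_m[None, :] - subj[:, None] + g) ** 2).sum())
    ss_subj = float(4 * ((subj - g) ** 2).sum())
    ss_res = ss_total - ss_site - ss_tpl - ss_int - ss_sa - ss_sb - ss_subj
    ss_res = max(ss_res, 0.0)

    return SomatotopyStats(
        site=_effect_from_contrast(subj, ss_site, ss_sa, ss_total),
        template=_effect_from_contrast(subj, ss_tpl, ss_sb, ss_total),
        interaction=_effect_from_contrast(subj, ss_int, ss_res, ss_total),
    )


def posthoc_paired(table, site: str) -> tuple[float, float, float, bool]:
    """Directional paired t of matched- vs mismatched-template responses.

    For ``site='hand'`` tests hand-template minus foot-template weighted
    hand-stimulation responses (right-tailed), and symmetrically for the
    foot. Returns (t, one-sided p, Cohen's d, degenerate-flag) with
    d = mean(diff) / SD(diff).
    """
    y = _as_cube(table)
    s = {"hand": 0, "foot": 1}[site]
    matched, mismatched = (0, 1) if s == 0 else (1, 0)
    diff = y[:, s, matched] - y[:, s, mismatched]
    r: ResponseTest = test_response(diff)
    d = r.mean / r.sd if r.sd > 0 else (np.inf * np.sign(r.mean) if r.mean else 0.0)
    return r.t, r.p, float(d), r.degenerate


def somatotopy_test(
    table, alpha: float = 0.05, force_posthoc: bool = False
) -> SomatotopyStats:
    """ANOVA plus post-hocs; post-hocs run only when the interaction is
    significant at ``alpha`` (override with ``force_posthoc``)."""
    st = rm_anova_2x2(table)
    post = None
    if force_posthoc or st.interaction.p < alpha:
        post = {site: posthoc_paired(table, site) for site in ("hand", "foot")}
    return SomatotopyStats(
        site=st.site, template=st.template, interaction=st.interaction, posthoc=post
    )


def top_channels(tpl: ChannelTemplate, k: int = 10) -> list:
    """The k channels with the largest template weights, descending."""
    if tpl.ch_names is None:
        raise ValueError("template carries no channel names")
    order = np.argsort(tpl.weights)[::-1][:k]
    return [tpl.ch_names[i] for i in order]


def _as_cube(table) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        piv = table.pivot_table(
            index="subject", columns=["site", "template"], values="value"
        )
        y = np.empty((len(piv), 2, 2))
        for i_s, s in enumerate(("hand", "foot")):
            for i_t, t in enumerate(("hand", "foot")):
                if (s, t) not in piv.columns:
                    raise ValueError(f"incomplete 2x2 table: missing cell {(s, t)}")
                y[:, i_s, i_t] = piv[(s, t)].to_numpy()
        if np.isnan(y).any():
            raise ValueError("incomplete 2x2 table: NaN cells")
        return y
    y = np.asarray(table, dtype=float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise ValueError("table must be (n_subjects, 2, 2)")
    if np.isnan(y).any():
        raise ValueError("incomplete 2x2 table: NaN cells")
    return y
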