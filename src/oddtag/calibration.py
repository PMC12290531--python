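"""Simulation studies validating the statistical chain.

Monte-Carlo calibration of the group tests (type-I error of the right-tailed
aggregate test and of the 2x2 within-subject interaction), the null behavior
of the oddball aggregate when only base-rate power is present, and
end-to-end parameter/somatotopy recovery on the synthetic study design.
These are the package's own verification experiments; they are exercised by
the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .freqtag import (
    aggregate_response,
    amplitude_spectrum,
    average_trials,
    baseline_subtract,
    build_harmonic_sets,
    test_response,
)
from .somatotopy import build_template, somatotopy_test, weight_response
from .synthetic import (
    NoiseSpec,
    SourceSpec,
    default_source,
    make_topography,
    simulate_dataset,
    simulate_trials,
)

__all__ = [
    "ttest_type1_error",
    "anova_interaction_type1_error",
    "base_only_oddball_null",
    "amplitude_recovery",
    "somatotopy_detection_rate",
]


def ttest_type1_error(
    n_subjects: int = 17,
    n_reps: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical rejection rate of the right-tailed one-sample t under the null.

    Zero-mean Gaussian per-subject aggregates; the rate should sit at the
    nominal alpha (vectorized across replicates).
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_reps, n_subjects))
    m = x.mean(axis=1)
    s = x.std(axis=1, ddof=1)
    t = m / (s / np.sqrt(n_subjects))
    p = stats.t.sf(t, df=n_subjects - 1)
    return float(np.mean(p < alpha))


def anova_interaction_type1_error(
    n_subjects: int = 17,
    n_reps: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the 2x2 within-subject interaction F.

    Exchangeable (iid) cells; uses the exact identity F(1, n-1) = t^2 of the
    paired t on per-subject double differences, which the full ANOVA
    reproduces, to vectorize the replicates.
    """
    rng = np.random.default_rng(seed)
    y = rng.standard_normal((n_reps, n_subjects, 2, 2))
    d = (y[:, :, 0, 0] - y[:, :, 0, 1]) - (y[:, :, 1, 0] - y[:, :, 1, 1])
    m = d.mean(axis=1)
    s = d.std(axis=1, ddof=1)
    F = (m / (s / np.sqrt(n_subjects))) ** 2
    p = stats.f.sf(F, 1, n_subjects - 1)
    return float(np.mean(p < alpha))


def _cell_oddball_spectrum(ep_data, rate, f_base=8.0, f_odd=1.6, fmax=40.0):
    avg = ep_data.mean(axis=0)
    spec = baseline_subtract(amplitude_spectrum(avg, rate, require_aligned=(f_odd,)))
    base, odd = build_harmonic_sets(f_base, f_odd, fmax, spec.bin_width)
    return spec, base, odd


def base_only_oddball_null(
    n_reps: int = 1000,
    n_subjects: int = 17,
    n_trials: int = 8,
    alpha: float = 0.01,
    rate: float = 125.0,
    duration: float = 40.0,
    seed: int = 0,
    noise: NoiseSpec | None = None,
) -> float:
    """Rejection rate of the oddball aggregate test with base-only power.

    Every simulated subject carries power only at multiples of 8 Hz; the
    oddball aggregate (multiples of 1.6 Hz excluding base bins) is then a
    true null and its right-tailed test should reject at the nominal rate.
    Subjects are simulated as independent single-electrode recordings.
    """
    noise = NoiseSpec(pink_scale=5.0, white_scale=2.0) if noise is None else noise
    base, odd = build_harmonic_sets(8.0, 1.6, 40.0, 1.0 / duration)
    src = SourceSpec(
        site="hand",
        topography=np.ones(n_subjects),  # one "channel" per subject
        base_freqs=base.frequencies,
        base_amplitudes=0.02 * np.ones(base.frequencies.size),
        oddball_freqs=odd.frequencies,
        oddball_amplitudes=np.zeros(odd.frequencies.size),
    )
    ss = np.random.SeedSequence([seed, 0xBA5E])
    rejections = 0
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        trials = simulate_trials(
            [src], noise, n_trials, duration, rate, rng=rng, dtype=np.float32
        )
        spec, _, odd_set = _cell_oddball_spectrum(trials, rate)
        vals = aggregate_response(spec, odd_set, scope="per_channel")
        if test_response(vals).p < alpha:
            rejections += 1
    return rejections / n_reps


def _dataset_responses(ds, f_base=8.0, f_odd=1.6, fmax=40.0):
    """Run the spectral chain on every cell of a simulated dataset.

    Returns (spectra, base_set, odd_set) where ``spectra`` maps
    (subject, site, condition) -> baseline-subtracted AmplitudeSpectrum of
    the trial average.
    """
    spectra = {}
    base_set = odd_set = None
    for ep in ds.iter_cells():
        subj = ep.meta["subject"].iloc[0]
        site = ep.meta["site"].iloc[0]
        cond = ep.meta["condition"].iloc[0]
        avg = average_trials(ep, by=None)["all"]
        spec = baseline_subtract(
            amplitude_spectrum(avg, ep.rate, require_aligned=(f_odd,))
        )
        if base_set is None:
            base_set, odd_set = build_harmonic_sets(f_base, f_odd, fmax, spec.bin_width)
        spectra[(subj, site, cond)] = spec
    return spectra, base_set, odd_set


def amplitude_recovery(
    seed: int = 0,
    rate: float = 125.0,
    n_subjects: int = 17,
    n_trials: int = 8,
    **dataset_kwargs,
) -> dict:
    """End-to-end recovery of injected harmonic amplitudes.

    Simulates the full study design, runs trial averaging, FFT and baseline
    subtraction, and compares grand-averaged (across subjects) channel-mean
    amplitudes at every injected harmonic against the ground truth. Returns
    the mean absolute relative error and the per-harmonic table.
    """
    ds = simulate_dataset(
        n_subjects=n_subjects,
        n_trials=n_trials,
        rate=rate,
        seed=seed,
        dtype=np.float32,
        **dataset_kwargs,
    )
    spectra, base_set, odd_set = _dataset_responses(ds)
    gt = ds.ground_truth

    rel_errors = []
    for site in ds.sites:
        for cond in ds.conditions:
            for kind, hset in (("base", base_set), ("oddball", odd_set)):
                sub = gt[(gt.site == site) & (gt.condition == cond) & (gt.kind == kind)]
                truth = sub.groupby("harmonic_hz")["channel_mean_uV"].mean()
                for f in hset.frequencies:
                    rec = np.mean(
                        [
                            spectra[(s, site, cond)].amplitudes[
                                :, spectra[(s, site, cond)].bin_index(f)
                            ].mean()
                            for s in range(ds.n_subjects)
                        ]
                    )
                    rel_errors.append(abs(rec - truth[f]) / truth[f])
    return {
        "mare": float(np.mean(rel_errors)),
        "n_harmonics": len(rel_errors),
        "n_subjects": ds.n_subjects,
    }


def somatotopy_detection_rate(
    n_runs: int = 50,
    seed: int = 0,
    rate: float = 125.0,
    distinct_topographies: bool = True,
    alpha: float = 0.05,
    localizer_condition: str = "frequency_intensity",
    test_condition: str = "spectrotemporal",
    **dataset_kwargs,
) -> dict:
    """Fraction of simulated studies recovering (or falsely finding) somatotopy.

    Per seeded run: templates are built from the localizer-condition base
    response per site, test-condition oddball responses are weighted by both
    templates, and the run counts as a detection when the site x template
    interaction is significant at ``alpha`` AND both directional post-hocs
    point the matched-template way. With ``distinct_topographies=False`` the
    same rate estimates the interaction's false-positive level.
    """
    ss = np.random.SeedSequence([seed, 0x50AA])
    detections = 0
    interaction_hits = 0
    for k, child in enumerate(ss.spawn(n_runs)):
        run_seed = int(child.generate_state(1)[0] % (2**31))
        ds = simulate_dataset(
            rate=rate,
            seed=run_seed,
            dtype=np.float32,
            distinct_topographies=distinct_topographies,
            **dataset_kwargs,
        )
        spectra, base_set, odd_set = _dataset_responses(ds)

        templates = {}
        for site in ds.sites:
            loc = [
                spectra[(s, site, localizer_condition)] for s in range(ds.n_subjects)
            ]
            templates[site] = build_template(
                loc, base_set, source_site=site, alpha=alpha, ch_names=ds.ch_names
            )

        cube = np.empty((ds.n_subjects, 2, 2))
        for s in range(ds.n_subjects):
            for i, site in enumerate(("hand", "foot")):
                resp = aggregate_response(
                    spectra[(s, site, test_condition)], odd_set, scope="per_channel"
                )
                for j, tpl_site in enumerate(("hand", "foot")):
                    cube[s, i, j] = weight_response(resp, templates[tpl_site])

        st = somatotopy_test(cube, alpha=alpha, force_posthoc=True)
        sig = st.interaction.p < alpha
        directions_ok = all(st.posthoc[site][0] > 0 for site in ("hand", "foot"))
        interaction_hits += int(sig)
        detections += int(sig and directions_ok)
    return {
        "detection_rate": detections / n_runs,
        "interaction_rate": interaction_hits / n_runs,
        "n_runs": n_runs,
    }
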