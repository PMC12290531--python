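# Methods notes

## Model and procedure

The package implements the analysis chain for fast periodic oddball
stimulation of the somatosensory system. A standard vibrotactile stimulus A
repeats at a base rate of 8 Hz; every fifth stimulus is a deviant B
(`AAAAB`), giving a deviant rate of 8/5 = 1.6 Hz; 64 loops make a 40-s
sequence. Steady-state responses are assumed to be (i) *phase-locked* to
sequence onset, so time-domain trial averaging preserves them while
attenuating background EEG by √n_trials, and (ii) *narrow-band*, confined to
exact multiples of the stimulation rates. Both assumptions are what justify
the spectral machinery: a 40-s epoch gives 0.025 Hz bins, every analysis
frequency (1.6, 3.2, …, 40 Hz) falls exactly on a bin (1.6/0.025 = 64), and
local baseline subtraction cancels any background whose amplitude varies
smoothly over a 27-bin (0.675 Hz) neighborhood.

Responses are quantified as the mean baseline-subtracted amplitude over a
harmonic set. The base set is every multiple of 8 Hz up to the 40 Hz cutoff
(the analysis band-pass edge): {8, 16, 24, 32, 40}. The oddball set is every
multiple of 1.6 Hz up to 40 Hz *excluding* base members (20 frequencies) —
base-rate activity is common to standards and deviants, so only the
remaining harmonics index discrimination. Aggregating across harmonics,
rather than reading a single bin, is deliberate: the shape of the periodic
response distributes its energy across harmonics, and different response
shapes move energy between them.

## Tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| `base_rate` | 8 Hz | standard repetition rate; slot length 125 ms |
| `pattern` | `AAAAB` | deviant every 5th slot → 1.6 Hz oddball rate |
| `n_loops` | 64 | sequence length 40 s |
| ramp | 15 ms | linear on/off ramp of each stimulus |
| noise band | 40–200 Hz | pass band of the spectrotemporal stimuli |
| band-pass | 0.1–40 Hz, order 4 | EEG cleaning filter (zero-phase) |
| resample | 500 Hz | analysis rate after cleaning |
| criterion | 500 µV | absolute-amplitude trial rejection |
| baseline window | ±(2..13) bins | 24 neighbors, 1-bin gap each side |
| `fmax` | 40 Hz | harmonic aggregation cutoff |
| template alpha | 0.05 | per-harmonic selection, right-tailed, uncorrected |

## Design choices where the design was open

* **Zero-phase filtering.** Stimulus and EEG Butterworth filters run
  forward–backward (`sosfiltfilt`). The stated order is the design order;
  the effective magnitude response is squared. Rationale: trial averaging
  and the envelope dissimilarity index both rely on undistorted phase.
* **FFT scaling.** One-sided amplitudes are 2|X_k|/N (|X_k|/N at DC and
  Nyquist) so a bin-aligned sinusoid of peak amplitude *a* reads *a* at its
  bin. Any fixed convention cancels in baseline subtraction and group
  statistics; this one makes injected amplitudes directly readable.
* **Noise-pair construction order.** Generate white noise → shuffle for the
  deviant → band-pass → RMS-normalize → ramp. Because ramping weights
  different samples in A and B, realized RMS after ramping is re-equalized
  exactly by a final scale-only step; the ramp's envelope time course is
  untouched.
* **Interpolation before re-referencing.** Bad channels are repaired from
  the three nearest good electrodes (3-D Euclidean montage distance,
  unweighted mean) on the continuous record. Interpolation and average
  referencing do not commute when a channel is bad (the bad channel
  contaminates the reference), so the chain order is fixed and enforced by
  the pipeline runner; a test demonstrates the non-commutativity.
  Interpolation commutes with epoching (pure slicing), so repairing the
  continuous record equals repairing just after segmentation.
* **2×2 repeated-measures ANOVA, closed form.** For the fully
  within-subject 2×2 design each effect has (1, n−1) df and its F equals the
  squared paired t of the corresponding per-subject contrast; the
  implementation computes the full sum-of-squares decomposition and is
  cross-checked in the tests against an independent general RM-ANOVA
  routine and against the t² identity. Both raw η² (SS_effect/SS_total) and
  partial η² are reported, since the bare symbol is ambiguous.
* **Group-level templates.** Channel templates are grand averages across
  subjects (one template per site, applied to every subject), built from
  the localizer condition only. Harmonic selection for templates is
  right-tailed at α = 0.05 without multiplicity correction — selection here
  is a weighting heuristic, not an inference.
* **Spearman correlation** for the envelope-dissimilarity vs oddball
  response relation: with seven sequences and a known outlier mechanism,
  ranks are the defensible choice.
* **Degenerate statistics contract.** Zero-variance inputs to the t-tests
  return t = ±∞ with the appropriate limiting p (0 for a positive mean in a
  right-tailed test) and a `degenerate` flag rather than NaN.
* **Out of scope.** Ocular-artifact ICA needs visual component selection
  and is not automated; the pipeline accepts externally cleaned data.
  Source localization is not computed: all statements are scalp-level.

## The synthetic generator

`synthetic.simulate_dataset` emulates the statistical structure the chain
assumes: 17 subjects × 2 stimulation sites × 2 conditions × 8 trials of
40-s, 64-channel recordings. Each cell contains strictly phase-locked
cosines at the base harmonics (amplitudes 0.35·e^(−f/30 Hz) µV at source
scale) and oddball harmonics (30 % of the base profile — deviant responses
are reliably the smaller), projected on site-specific scalp bumps — a
left-central bump between C3 and C1 for the hand, a midline bump between Cz
and CPz for the foot — plus fresh 1/f + white noise per trial and channel.
Between-subject variability is a multiplicative log-normal jitter
(σ = 0.3) per subject × site × condition × response kind. Per-trial
"contrast detected" labels are drawn at 0.7 (frequency–intensity) and 0.375
(spectrotemporal), the rates such experiments report behaviorally. These
defaults put channel-averaged aggregated responses in the 10⁻³–10⁻² µV
range, the order real recordings of this paradigm yield.

Two generator choices deserve emphasis because they define what the
validation studies do and do not show:

* **Topographies are compactly supported** (Gaussian bump with gains below
  15 % of the peak set to zero, unit norm, ~12 active electrodes). Real
  scalp fields have diffuse tails; a simulated tail electrode whose signal
  sits below the noise floor can never be recovered by a magnitude-based
  method, which would make channel-averaged ground truth ill-defined.
* **The noise defaults are low** (pink 0.1 µV, white 0.05 µV RMS per trial
  and channel — the residue left after preprocessing and artifact control,
  not raw scalp EEG). The reason is a genuine property of the
  quantification method: spectra are *magnitudes*, so at a response bin the
  baseline-subtracted estimate is E|S + N| − E|N| ≈ |S| − 1.25σ·(…), a
  systematic downward (Rician) bias whenever per-channel noise σ is not
  small against the per-channel signal. The bias shrinks with trial count
  but not with subject count. The default regime is near-asymptotic so that
  injected amplitudes are recoverable and bookkeeping errors are visible;
  raising the noise knobs reproduces the biased regime, and analyses of
  real data inherit that bias. Consequently, passing recovery tests
  demonstrates correctness of the chain's arithmetic — not that real
  single-subject recordings at realistic noise support unbiased amplitude
  estimates.

Other real-data features the generator does not emulate: non-stationary and
spatially correlated noise (a spatial-correlation kernel is exposed as a
knob but off by default), ocular artifacts, imperfect phase locking, and
volume-conduction lead fields (bumps are geometric, not biophysical).

## Simulation-study problem sizes

The calibration studies run the generator at a 125 Hz simulation rate with
float32 noise: a 40-s epoch then has 5000 samples, preserving the 0.025 Hz
bin grid and the entire 40 Hz analysis band (Nyquist 62.5 Hz) while keeping
fifty-run detection studies tractable on one core. Type-I calibrations use
10 000 vectorized replicates at n = 17; the base-only null uses 1000
simulated 17-subject experiments; recovery and somatotopy studies use the
full 17 × 2 × 2 × 8 design.

## Known limitations

* Spectral quantities assume exact bin alignment; misaligned fundamentals
  raise errors rather than silently leaking.
* The amplitude-recovery bias above is intrinsic to magnitude spectra with
  noise; the package reports it rather than correcting it (no complex-domain
  estimator is provided).
* EDF export is not implemented (reading is); synthetic exports use the
  portable `.npz` epoch container, delimited matrices and TSV tables.
* `resample` only downsamples (polyphase, anti-aliased); the chain never
  needs upsampling.
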