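# Methods

`pulsebp` implements a feature-based, cuffless blood-pressure (BP)
estimation pipeline for radial pulse waveforms recorded by a small
tonometric sensing array, together with a synthetic-data generator that
stands in for the (non-public) human study such pipelines are trained
on. This note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## Pipeline overview

Five stages, each an importable module:

1. **Acquisition (simulated)** — `pulsebp.simulate` produces
   multi-channel recordings with paired cuff-reference SBP/DBP.
2. **Preprocessing** — `pulsebp.emd` selects the best-aligned channel
   and removes baseline wander, high-frequency noise and artifact
   energy by empirical mode decomposition (EMD) and partial
   reconstruction.
3. **Feature extraction** — `pulsebp.features` segments beats, locates
   six fiducial landmarks per beat and computes eleven features.
4. **Regression** — `pulsebp.models` fits random-forest (RFR),
   gradient-boosting (GBR) and AdaBoost (ABR) regressors, separately
   per target (SBP, DBP), on an 80/20 split.
5. **Agreement analysis** — `pulsebp.evaluate` reports R²,
   Bland–Altman bias with 95% limits of agreement, and the fraction of
   estimates within 5/10/15 mmHg of the reference.

## Synthetic data generator

### Beat template

One beat is the sum of two Gaussian bumps (systolic and dicrotic) on a
diastolic baseline, plus a late-diastolic run-off:

    y(t) = b + A_s exp(−(t−t_s)²/2σ_s²) + A_d exp(−(t−t_d)²/2σ_d²) + R(t)

with default widths σ_s = 45 ms and σ_d = 65 ms. The run-off `R`
declines linearly from the dicrotic complex and finishes as the exact
time-mirror of the systolic foot, so consecutive beats meet in a
*symmetric* V-shaped trough. This detail matters: the denoiser is a
band-limiting operation, and the minimum of a band-limited asymmetric
V is biased toward its shallower side, which would corrupt the onset
(diastolic point 1) and end (diastolic point 2) landmarks by several
samples no matter how the detector is built. With a symmetric V the
trough position is invariant under band-limiting and symmetric noise.

The six true landmark times (onset, maximum-slope point, systolic
peak, dicrotic notch, dicrotic peak, end) are derived *numerically*
from the sampled template, and the onset/end troughs are re-derived on
the concatenated clean signal (at a beat junction the true minimum is
the junction sample, which can differ by one sample from the isolated
template's own argmin). These form the ground-truth ledger that every
downstream accuracy test is scored against.

### BP → morphology map

The paper-scale physiology linking waveform shape to BP is unknown, so
the generator uses an explicit, monotone, affine map (units: mmHg in,
template units out):

| quantity                     | map                          |
|------------------------------|------------------------------|
| systolic amplitude `A_s`     | 0.50 + 0.012·(SBP − 118)     |
| dicrotic/systolic ratio      | 0.28 + 0.006·(DBP − 70)      |
| time-to-peak `t_s` (s)       | 0.130 − 0.0008·(PP − 45)     |
| dicrotic time `t_d` (s)      | 0.350 + 0.0015·(DBP − 70)    |
| onset baseline (units)       | 0.05 + 0.002·(DBP − 70)      |

(PP = pulse pressure = SBP − DBP.) SBP therefore drives the systolic
amplitude and the maximum upstroke slope; DBP drives the augmentation
ratio and the dicrotic timing. The map is invertible by construction,
which is what makes end-to-end parameter recovery a meaningful test:
a pipeline that measures the features faithfully *can* recover BP, and
failure to do so indicts the pipeline, not the data.

### Study conditions (defaults)

23 subjects × 49 recordings (1127 records); per-subject mean SBP
uniform in [103, 133] mmHg and DBP in [62, 77] with ±5/±4 mmHg
per-record excursions, so the corpus spans SBP 98–138 / DBP 58–81 and
subjects cluster as real participants do. Recordings are 10 s at
250 Hz (the acquisition rate of the emulated device is not public;
250 Hz is typical for tonometry and comfortably resolves the
waveform), heart rate 55–85 bpm with per-beat lognormal period jitter
(σ = 0.03, strictly positive periods). Each recording carries one
SBP/DBP pair; a "record" is one 10-s window, and per-record features
are the componentwise **median over its beats** (~10–14), which is
robust to occasional corrupted beats.

Corruptions: white Gaussian noise with SD 5% of the systolic
amplitude (a moderately noisy but usable tonometric trace); sinusoidal
baseline wander at 0.1 Hz with amplitude 20% of the systolic amplitude
(respiration/movement-scale drift); with probability 0.02 per beat, a
damped 15 Hz transient (motion artifact) shared by all channels.
Channel gains default to (0.35, 1.00, 0.45): exactly one element of
the 3-channel array is well-aligned, the neighbours see an attenuated
copy under the same additive corruptions.

### What the generator does *not* emulate

No Windkessel/transmission-line hemodynamics, no sensor physics, no
respiration-modulated amplitude, no inter-subject morphology variation
beyond the BP map, and a BP→shape relation that is far cleaner than
physiology. Passing tests therefore demonstrate that the pipeline
measures what the waveform encodes — not that these three regressors
would reach any particular accuracy on human data. The headline R²
values on this corpus (≈0.99 SBP / ≈0.89 DBP) are properties of the
synthetic map's cleanliness and should not be compared with clinical
studies.

## EMD denoising

Classical sifting: cubic-spline envelopes through maxima/minima with
two extrema mirrored about each end point, mean-envelope subtraction,
Cauchy-type stop `SD = Σ(h_{k−1}−h_k)²/Σh_{k−1}² < 0.2` (iteration cap
100), decomposition stops when the residue has fewer than two maxima
or minima, or at 12 modes. The stop threshold is deliberately not
tightened: forcing each mode to exact extrema/zero-crossing balance
over-sifts noisy pulse signals (beat energy drains into the fast
modes) and measurably degrades both denoising and landmark accuracy;
with the Cauchy stop the balance holds to within a few percent of the
extrema count, which is the behaviour asserted in the tests.

Each mode is classified by its dominant frequency (half the
zero-crossing rate): **noise** above the pulse band, **baseline**
below it (the residue is always baseline), **signal** inside. The
denoised signal is the sum of the signal modes only.

The default band is **0.7–12 Hz**. Both edges sit in the empirical
spectral gaps between the three component classes: wander-dominated
modes register at ≲0.5 Hz on the zero-crossing estimator, beat content
spans ≈0.9–9 Hz (fundamentals for 55–85 bpm plus the harmonics that
carry systolic/dicrotic detail; radial-pulse energy is essentially
contained below ~12 Hz), and sensor-noise modes sit above 25 Hz. An
upper edge at 8 Hz — the narrowest defensible choice — intermittently
discards the highest-energy beat-detail mode (dominant frequency can
reach 8–9 Hz), halving beat amplitude on some records; a lower edge at
0.5 Hz keeps wander modes whose estimated frequency lands exactly on
the edge. Recordings with rhythms slower than ~45 bpm need the lower
edge reduced (config `emd.beat_band_hz`).

Channel selection ranks channels by *mean Pearson correlation of each
detected beat against the channel's median beat shape, times the
median beat peak-to-trough amplitude* — an operationalisation of
"distinguishable peaks, least noise". Detection for ranking runs on a
lightly band-passed copy (0.5–10 Hz zero-phase Butterworth); the
pipeline's actual denoiser is EMD. Ties break to the lowest index.

## Fiducial detection and features

Beats are delimited by onset troughs. Systolic peaks are found first
(minimum separation 60/HRmax s, prominence 25% of the robust range);
the onset trough for each peak is then located **within the last 45%
of the preceding peak-to-peak interval** (the onset immediately
precedes the upstroke; a full-interval minimum search can be captured
by a deep dicrotic notch when the baseline tilts). The trough is
seeded on a 9-sample Hann-smoothed copy — residual in-band noise makes
a raw argmin wander across the shallow valley — and pinned to the raw
signal's minimum within ±4 samples of the seed. All amplitudes and
slopes are read from the unsmoothed signal.

Within a beat: onset = first sample; systolic peak = first prominent
maximum (ties → earliest); maximum-slope point = argmax of the first
difference between onset and peak (slope = difference × sampling
rate, no additional smoothing); dicrotic notch = first local minimum
after the peak and dicrotic peak = first local maximum after the
notch, both with a 5% prominence floor so residual-noise wiggles are
not mistaken for landmarks; end = last sample. Beats violating the
landmark ordering or lacking a dicrotic complex are flagged degenerate
and excluded; a record needs ≥3 valid beats or it is rejected with a
reason code.

Features (per beat, then median over beats): heart rate = 60 / the
systolic-peak-to-peak interval with the previous beat (the first beat
inherits the record's median interval); systolic, dicrotic, notch and
end amplitudes as offsets from the onset amplitude (the onset
amplitude itself is kept in raw units); maximum upstroke slope;
augmentation index = systolic/dicrotic offset ratio (the literal
reading of the feature's definition; the inverse convention is a
config switch `features.ai_convention`); T1 = onset→systolic,
T2 = systolic→dicrotic, T3 = dicrotic→end time intervals. With the
onset as amplitude baseline, the augmentation index is invariant to
both signal offset and overall scale.

## Regression and split protocol

Scikit-learn ensembles, one model per (algorithm, target): RFR with
100 unconstrained-depth trees; GBR with 100 depth-3 learners at
learning rate 0.1; ABR over depth-3 trees, 100 learners. No
hyperparameter search; everything is exposed in the config. The split
is record-level by default, `round(0.8·n)` training rows (Python's
round-half-even), drawn uniformly with a derived seed. A subject-level
split mode keeps each participant's records on one side (never
absorbing the final subject into training, so the test side cannot be
empty); with ~49 records per subject the record-level protocol shares
every subject across folds, so the subject mode is the harder,
leakage-free comparison and is reported alongside it by the analysis
driver (on this corpus: SBP R² ≈0.99 record-level vs ≈0.96
subject-level).

## Agreement statistics

Differences are `estimate − reference` throughout. R² is
`1 − SS_res/SS_tot` about the reference mean (undefined → NaN when the
reference has zero variance). Bland–Altman: bias = mean difference,
limits = bias ± 1.96 × sample SD (n−1). Error bands count
`|difference| < threshold` **strictly**; a difference exactly at a
threshold falls outside the band. Tables render percentages to one
decimal, one row per algorithm; plots (scatter with identity line,
Bland–Altman with bias/LoA lines) are best-effort artifacts, the
numeric report is the contract.

## Numerical and degenerate-input choices

* Indices are 0-based; time = index / sampling rate.
* EMD of a constant, monotone or <8-sample signal returns zero modes
  with the input as residue; a channel whose modes are all
  noise/baseline raises `UnusableChannelError`.
* Spline envelopes mirror two extrema about each end sample; mirrored
  knots that coincide with interior knots are deduplicated.
* Plateaus in extrema detection collapse to the sign of the slope that
  ends them.
* Fiducial amplitude ordering (systolic ≥ dicrotic ≥ notch) is
  enforced with 1% slack so equal-height peaks sampled off-grid count
  as ties, not violations.
* Every stage's randomness derives from one global seed via
  `SeedSequence`; identical config ⇒ byte-identical feature CSV.

## Problem sizes

Default corpus 1127 records (≈25 s end-to-end on one core); the
supporting measurements use 100 recordings for channel selection, 20
for denoising efficacy, and the full corpus for landmark accuracy and
BP recovery. These sizes give stable estimates of each quantity while
keeping a full run interactive.

## Known limitations

* The dominant-frequency classifier (zero-crossing rate) is coarse for
  slow modes; band edges are therefore placed in spectral gaps rather
  than at physiological limits.
* EMD mode-mixing leaves a few percent of wander in the signal modes
  on unfavourable phase alignments (worst observed: ~6% of sub-0.3 Hz
  power retained).
* The onset V of real pulses is not symmetric; on human data the
  onset/end landmarks would carry a systematic detector-dependent
  offset that cancels in T-interval *differences* across conditions
  but not in absolute values.
* Subject-level generalisation is only as hard as the synthetic
  subject model (a per-subject BP mean); real inter-subject morphology
  differences are absent.
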