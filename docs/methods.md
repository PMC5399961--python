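# Methods

## The procedure

Scalp EEG recorded during seizures is frequently unreadable because scalp
and facial muscle (EMG) activity — broadband, strongest above ~16-20 Hz,
and spatially focal at the generating muscle — swamps the neurogenic
signal. The method implemented here exploits exactly those two properties
(spectral concentration above 16 Hz, spatial focality) to remove muscle
artifact automatically:

1. **Analysis band.** The referential recording is band-pass filtered
   16-70 Hz with an even-order (default 500) Hamming windowed-sinc FIR
   filter, applied in one forward pass and advanced by the group delay
   (order/2 samples) so the output is time-aligned with the input.
2. **Artifact epoch.** Per channel, the Hilbert instantaneous amplitude
   is z-scored over the record; the z-scored envelopes are averaged
   across channels, smoothed with a centered moving average (default
   0.5 s), and the smoothed composite is rescaled to zero mean and unit
   SD. The longest run of samples strictly above 1 SD is the artifact
   epoch. The final rescaling matters: averaging z-scores across
   channels shrinks the composite's variance by roughly the fraction of
   artifact-free channels, so a threshold "in SD units" is only
   meaningful on the scale of the composite series itself. Without it,
   the detector's sensitivity would depend on how many channels happen
   to carry artifact.
3. **Channel screening.** Within the artifact epoch, a normalized
   mutual information (NMI) adjacency matrix is computed across all
   channel pairs of the band-passed data (equal-width histogram,
   default 16 bins per axis; plug-in MI in nats normalized by
   `sqrt(H(X)H(Y))`). A channel's quality score is its maximum pairwise
   NMI; channels below the inclusion threshold (default 0.2) share no
   signal with any other electrode — the signature of a high-impedance
   contact — and are excluded from decomposition. If there is no usable
   epoch, or screening would exclude everything, all channels are
   processed (fallback).
4. **Band split.** The recording is split at 16 Hz. The low band is the
   zero-phase low-pass output; the high band is defined as input minus
   low band, so the two add back to the input exactly — reconstitution
   is lossless whenever nothing is pruned.
5. **Per-trial ICA.** The high band of the included channels is cut into
   consecutive 120-s trials (24,000 samples at 200 Hz; a final remainder
   shorter than half a trial is merged into the last full trial) and
   each trial is decomposed with natural-gradient Infomax ICA: mean
   centering, PCA whitening (dimensions below 1e-9 of total variance
   dropped), logistic nonlinearity, runica-style annealing (rate cut by
   2% when successive weight updates differ by more than 60 degrees),
   convergence when the squared weight change falls below 1e-6, at most
   512 iterations. An extended variant with adaptive sub/super-Gaussian
   source signs is available (`extended_infomax`) but off by default.
   Runs are deterministic given the seed; each trial uses `seed +
   trial_index`.
6. **Focality classification.** Each component's mixing ("inverse
   weight") column is its scalp topography. Columns are flipped so the
   largest-magnitude electrode is positive (component polarity is
   arbitrary in ICA), then z-scored across electrodes (population SD).
   A component whose topography reaches 2 SD at any electrode is
   myogenic and removed. Two decision modes exist: `per_component`
   (default; each component tested independently) and `variance_prefix`
   (myogenic components assumed to occupy a contiguous prefix of the
   explained-variance ordering, pruned up to the last focal one). The
   default never removes a non-focal component.
7. **Reconstitution.** Kept components are back-projected, trials are
   concatenated without cross-fading (boundary discontinuities are
   possible and accepted), and the cleaned high band is added to the
   untouched low band. Excluded channels pass through with their
   original signal, flagged in the report — clinical reviewers expect
   every trace present. Output is written as 16-bit EDF with a
   provenance string in the recording-id header field.

## Parameters

| parameter | default | unit | note |
|---|---|---|---|
| `band_low_hz` / `band_high_hz` | 16 / 70 | Hz | analysis band; upper edge clipped to 0.45 fs below 156 Hz |
| `fir_order` | 500 | taps−1 | even, linear phase |
| `envelope_threshold_sd` | 1 | SD of composite | strict inequality |
| `smooth_window_s` | 0.5 | s | forced to an odd sample count |
| `mi_bins` | 16 | — | equal-width histogram per axis |
| `mi_inclusion_threshold` | 0.2 | NMI | inclusive comparison |
| `trial_s` | 120 | s | 24,000 samples at 200 Hz |
| `focality_threshold_sd` | 2 | SD over electrodes | inclusive |
| `ica_tol` / `ica_max_iter` | 1e-6 / 512 | — | squared weight-change / iterations |
| `seed` | 0 | — | echoed in every run report |

The envelope smoothing window, MI estimator settings and the inclusion
threshold are the method's open parameters (no published values); the
defaults above are recorded in every run report so a run is reproducible
from its report alone.

## The synthetic scenes

`simulate_scene` builds additive scenes whose parts are returned exactly
(`scene = neurogenic + emg + background + badnoise`, bitwise):

* **neurogenic**: one narrowband (20-30 Hz) source that ramps up over
  20 s from the onset time, topography `exp(-d²/2σ²)` on a 2-D 10-20
  layout, σ = 0.9 head radii. The ramp makes the source super-Gaussian
  (stationary band-limited Gaussian noise would be unidentifiable by
  ICA — and unphysiological: ictal rhythms wax). At σ = 0.9 the true
  topography's maximum electrode z-score is ≈ 1.67, i.e. distributed by
  construction, comfortably inside the 2 SD focality boundary.
* **EMG**: bursts of 20-95 Hz noise over a muscle group (default
  alternating left/right temporalis, F7/T3 and F8/T4, 5-s bursts every
  15 s at 60 µV). Each burst drives a common source on its two
  electrodes (weights 1.0/0.7, topography z ≈ 3.4) plus smaller
  independent per-electrode noise (one-hot, z ≈ 4.24): EMG-active
  channels stay mutually informative — as volume-conducted muscle
  potentials at neighbouring electrodes are — while remaining focal.
* **background**: 8 spatially smooth 1/f sources (σ = 0.6) scaled to
  10 µV per-channel RMS, plus 2 µV independent white sensor noise.
  Shared background is essential: mutual-information screening detects
  a dead channel only because live channels share volume-conducted
  signal.
* **bad channels**: electrodes replaced wholesale by 30 µV independent
  white noise.

The generator is a fixture, not a forward model: no head geometry (the
layout coordinates are a documented 2-D convention), no motor-unit
physiology, no ocular or cardiac artifact, no line noise. Passing tests
therefore demonstrate that the algorithm separates focal broadband
artifact from distributed narrowband rhythm under the spatial and
spectral assumptions the method encodes — not that it handles every
failure mode of clinical recordings.

## Scoring cleaning

`score_cleaning` reports, per channel, the correlation of the cleaned
signal with the neurogenic truth over the ictal interval (*retention*),
and two suppression numbers, both capped at 60 dB:

* `suppression_db`: >16 Hz power of (scene − neurogenic) before vs
  after cleaning. This ratio counts retained background against the
  cleaner: even an oracle that removes all EMG but keeps the background
  is capped at `(EMG + background)/background` at that electrode.
* `emg_excess_suppression_db`: the same ratio on the power in excess of
  the background + bad-channel truth. This isolates the EMG actually
  removed and is the number to read for artifact-removal performance.

## Numerical choices

* Half-open sample intervals, 0-based, everywhere.
* EDF encoding uses a symmetric digital range (−32767..32767) so 0 µV
  is exact; the physical range is symmetric, padded ≥ 1%, and rounded
  up to 5 significant digits so the 8-character header field parses
  back to the exact range used for quantization. Worst-case round-trip
  error is half a quantization step.
* Envelope threshold: strictly greater; channel inclusion and focality:
  greater-or-equal; epoch ties: earliest run wins.
* A channel that is constant inside the artifact epoch gets NMI 0
  against everything (screened out as dead) rather than raising.
* Whitening dimensions below 1e-9 of total variance are dropped; an
  exactly duplicated channel yields a reduced-rank decomposition.
* Trial channel means are removed before ICA and restored on
  back-projection; otherwise the no-op configuration (infinite focality
  threshold) would subtract each trial's mean from the output.
* Non-convergent trials proceed with the final weights and a recorded
  warning; the pipeline never aborts on non-convergence.

## Known limitations

* The plug-in NMI estimator is bias-inflated for short epochs (roughly
  `(bins−1)²/2N` nats): on epochs of a few hundred samples, independent
  channels can score above the 0.2 threshold. The epoch-length guard
  (4·bins samples) is a floor, not a cure; heavily contaminated records
  with sustained artifact give the long epochs the estimator needs.
* Trials are cleaned independently; component selections can differ
  across trial boundaries, producing visible discontinuities.
* Under the unit-SD composite convention, some run above 1 SD almost
  always exists; "no artifact epoch" arises for degenerate amplitude
  profiles (flat or dropout-dominated records), and short pseudo-epochs
  in quiet records are routed to fallback by the epoch-length guard.
* Stationary Gaussian high-band activity is unidentifiable by ICA; the
  method relies on artifact being bursty/non-Gaussian, which EMG is.

## Problem sizes used in the checks

The automated checks run the full pipeline on the default 19-channel,
300-s, 200-Hz scene (three 120-s trials after remainder merging), the
ICA recovery study on 3 × 24,000-sample Laplacian mixtures over 10
seeds, and the screening study on one hundred 60-s scenes with sustained
bilateral temporalis artifact and one dead electrode.
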