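# Methods

## Modified Z-scoring against the quietest period

Every downstream quantity operates on modified Z-scores rather than raw ΔF/F.
The normalizer is the cell's own *quietest period*: the contiguous window
(default 10 s, `round(window_s × frame_rate)` frames, sliding by one frame)
minimizing the sample standard deviation (ddof = 1) of ΔF/F. "Lowest
variation" is interpreted as minimum sample SD; minimum variance has the
identical argmin, so the choice only fixes the convention of the reported
`quiet_sd`. Ties break to the earliest window start. The search runs over the
full session trace by default (spontaneous and evoked blocks concatenated); a
flag restricts it to a sub-block.

The transform is affine and order-preserving, so it leaves Pearson
correlations and rank statistics untouched. A quietest-window SD at or below
1e−9 marks a dead or constant ROI: the library either raises
`DegenerateTraceError` or flags the row (`on_degenerate="nan"`), and the
batch classifier reports such cells as flagged rows rather than aborting.

One consequence worth knowing: because the quietest window is the *minimum*
over many overlapping windows, its SD underestimates the global noise SD by
roughly 10–15% at 7.8 Hz over ~90 s, so the Z-noise SD is slightly above 1.
The event threshold (Z > 3) therefore corresponds to ≈ 2.6–2.8 true noise
SDs. This motivates the epoch gate in per-stimulus response detection (below).

## Activity epochs and peak calls

An activity epoch is a maximal run of at least 4 consecutive frames with Z
strictly above 3 ("above three" is implemented as strict inequality; both
parameters are configurable). Epochs are half-open `[start, end)` intervals in
0-based frames, a convention used throughout.

Peaks are interior local maxima filtered by amplitude (`min_height`, default
Z = 3) and topographic prominence (`selectivity`): a maximum must rise above
the higher of its flanking valley minima — scanned until a taller sample or
the segment edge — by at least the selectivity. `"auto"` selectivity is
(max − min)/4 of the analyzed segment. Where several peaks fall in one
analysis window the largest amplitude wins, ties to the earlier frame.
Plateau maxima report their left edge; segments shorter than 3 frames have no
interior maximum and yield no calls.

## Scramble-bootstrap classification of stimulus-locked cells

The stimulus is represented as a binary boxcar at the imaging frame rate:
frame k is 1 iff its acquisition time lies in `[onset, onset + duration)` of
some epoch. The 10 Hz fine structure of the deflection train is not
represented — it is unresolvable at ~7.8 Hz imaging.

For each cell the observed statistic is the Pearson correlation between the
Z trace and the boxcar. The null is built by scrambling the trace while
preserving every activity epoch intact. Two mechanisms are provided:

* **block** (default): the trace is cut at epoch boundaries into alternating
  background and epoch blocks whose order is permuted uniformly. Length and
  the multiset of sample values are preserved exactly.
* **replace**: background samples are shuffled individually and epochs are
  re-inserted contiguously at uniformly chosen offsets (all offsets chosen
  before insertion, so epochs cannot fragment one another).

A cell is stimulus-locked iff its observed correlation *strictly* exceeds the
`⌈(1 − α)·n⌉`-th order statistic of the n scrambled correlations (top 1% with
the defaults α = 0.01, n = 10,000; n ≥ 1,000 is accepted for faster runs, and
the mean/SD of the trace are scramble-invariant, so each scramble costs one
dot product).

Strictness makes the test conservative for cells with few epochs: a cell with
k epochs has at most (2k + 1)! distinct block arrangements, and with one
epoch the observed arrangement ties the null maximum so the cell can never be
flagged. On stimulus-independent cells the realized false-positive rate is
therefore at or slightly below the nominal 1% (the acceptance script measures
it at ≈ 0.4–0.8% on 500 cells). Batch classification draws independent RNG
substreams per cell from one master seed, so verdicts are reproducible and
order-independent.

## Evoked-response metrics

Z segments of `[onset, onset + 2 s)` are stacked per stimulus; the mean
stimulus-evoked trace is their frame-wise mean. AUC is the trapezoidal
integral with dx = 1/frame_rate, reported in Z·s. No baseline subtraction is
applied before integration (optional flag). The per-stimulus detection window
equals the AUC window (2 s fits inside the 4 s stimulus period, so windows
never overlap).

A stimulus epoch counts as *responded* when a peak call inside its window
also lies within an activity epoch of the full trace. The epoch gate is this
package's design choice: without it, the slightly super-unit Z-noise
(see above) false-alarms on ≈ 10% of event-free windows; with it, measured
per-window specificity on synthetic data is ≈ 1.00 and sensitivity ≈ 0.99 at
SNR 8 (the alternative — deriving selectivity from the whole-trace range —
costs a quarter of true weak events). The gate is exposed as
`require_epoch=True`.

Peak amplitude and latency (peak frame minus onset frame, in s) average over
responded epochs only; a cell with no responded epoch carries NaN and an
explicit flag. The adaptation index uses the summed AUC of stimuli 1–5 (A)
and 16–20 (B): `(A − B)/(A + B)`, undefined (flagged, never silent NaN) when
A + B = 0. For a geometric amplitude decay γ per stimulus the analytic value
is `(1 − γ^15)/(1 + γ^15)`, which the recovery tests verify.

## Spontaneous metrics

Transient rate (events/min by default), mean peak amplitude, and total
trapezoidal AUC over the whole spontaneous block (≥ 10 s required), using the
same peak parameters as evoked detection.

## ISI map quantification

Per trial and pixel, ΔR/R = (mean post-stimulus − mean pre-stimulus) / mean
pre-stimulus reflectance, averaged over trials (the acquisition windows are
0.9 s pre / 1.5 s post at 30 Hz, 30 trials; the ratio construction itself is
this package's choice since only the windows are standard). Pixels with a
non-positive baseline are excluded as NaN. The image is standardized to Z
over all valid pixels (optional background-ROI standardization), the map is
`Z < −3`, area is pixel count × pixel_size², and map intensity is the mean
over the map divided by the mean over the background outside it, with a
user-supplied fallback ROI when no map survives thresholding. No spatial
smoothing is applied by default. On a noise-free Gaussian-blob phantom the
thresholded area has the closed form `π r*²` with
`r*² = −2σ² ln((−3·sd + μ)/A)`, which the calibration tests use.

## Synthetic-data generator

The generator emulates the recording structure this pipeline targets: ~7.8 Hz
imaging, 20 stimulus epochs of 1 s separated by 3 s, ~100 s spontaneous
blocks, ~32 active cells per FOV, and ISI sessions of 30 trials at 30 Hz.
Traces are sums of unit-peak difference-of-exponentials transients
(rise 0.18 s, decay 1.5 s — GCaMP6s-like generator defaults, not measured
values; equal time constants fall back to the α-function limit `t·e^(−t/τ)`)
plus white Gaussian noise on ΔF/F. Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| frac_responsive | 1/3 | observed responsive fractions in principal-barrel FOVs |
| response_prob | 0.23 | observed per-stimulus response rate |
| evoked_amp_mean | 0.8 ΔF/F | puts locked-cell evoked AUC at ~6 Z·s, in the observed several-Z·s range |
| amp_cv | 0.3 | lognormal amplitude jitter so recovery tests are non-degenerate |
| adaptation_factor | 0.95 | mild within-train decrement; not pinned by data |
| spont_rate | 0.05 /s | sparse spontaneous transients under light anesthesia |
| noise_sd | 0.05 ΔF/F | evoked SNR 16, spontaneous SNR 8 |
| evoked_jitter_s | 0.25 s | onset-locked responses: short latency plus early-deflection dominance |

Evoked onsets are drawn uniformly from `[0, evoked_jitter_s]` after epoch
onset. This width matters: the scramble classifier's power collapses if
response latency is spread over the whole 1 s epoch (sensitivity falls from
≈ 1.0 at ≤ 0.3 s jitter to ≈ 0.03 at 1 s, because the transient mass leaves
the stimulus boxcar), and onset-locked responses are the physiologically
expected case for brief deflection trains under sensory adaptation.

Every transient is logged in the per-cell ground truth (epoch index, time,
amplitude), so count-conservation and recovery are directly assertable.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: photobleaching or hemodynamic drift (an optional
sinusoidal drift term exists but defaults off), correlated (pink) noise,
neuropil contamination, motion artifacts, and heterogeneous per-cell response
reliability. The last one is consequential: with a homogeneous per-stimulus
probability of 0.23, the permutation null is wide (few aligned events) and
classifier sensitivity saturates near 0.5 regardless of amplitude, so default
FOVs yield ~15–19% locked cells rather than the ~33% seen in vivo, where a
reliability spectrum lets the reliable minority carry the population count.
Matching the locked fraction and the mean response rate simultaneously would
require a response-probability distribution, which we deliberately did not
fit.

## Problem sizes and numerical choices

The validation suite runs at desk scale by choice: 500 null cells × 2,000
scrambles for false-positive calibration, 150–200-cell FOVs with 1,000
scrambles for recovery, 1,000 random traces per brute-force oracle, 10,000
scrambles for the conservation laws, and 128×128 phantoms for ISI
calibration. Quantile index: `⌈(1 − α)n⌉` computed with a 1e−12 guard against
binary-float artifacts (0.99 × 2000 is not exactly 1980 in binary). All RNG
flows through `numpy.random.Generator` with `SeedSequence` spawning for
per-cell substreams; identical seeds give bitwise-identical outputs, which
the determinism tests assert at the file level. Epoch boundaries, frame
indices, and times are 0-based, half-open, and in seconds everywhere.

## Known limitations

* The exact scramble construction of the original MATLAB analysis is not
  recoverable; block permutation is the default and epoch re-placement the
  alternative (`scramble_mode="replace"`). Both satisfy the stated
  conservation laws.
* Correlation uses the evoked-block trace it is given; whether the original
  analysis included spontaneous frames in the correlated vector is unknown.
* The ISI branch implements the raw-ΔR/R analysis only, not the
  intensity-scaled variant used when raw images are unavailable.
* Group-level inference (mixed models, multiple-comparison correction) is out
  of scope; `summaries` emits tidy per-mouse tables for external statistics
  packages.
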