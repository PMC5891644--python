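# Methods

## The system being modelled

The package reproduces, in software, a rehabilitation platform in which a
chronic-stroke user triggers an elbow orthosis (and an FES unit for hand
opening) by *simultaneously* imagining the movement — detected by a
motor-imagery EEG classifier — and pushing the forearm in the required
direction against a force sensor. That conjunction ("BF control") is the
unit gate of three goal-oriented training protocols. Around it sit an
offline decoder-search stage, an online decision chain, a hemispheric EEG
symmetry measure, and single-case outcome statistics. Hardware (motors,
stimulation electronics, acquisition drivers) is out of scope; FES timing
constants appear only as scheduled events in trial logs.

## Generative EEG model

A recording is the sum of

- **rhythm sources**: one mu and one beta sinusoid with random phase and a
  slowly varying positive envelope (knots every 2 s, 15% modulation),
  projected with unit gain to every channel of the montage;
- **ERD gating**: channels listed in `erd_channels` have their rhythm
  multiplied by (1 − `erd_depth`) inside imagery-cue windows, so imagery
  band power on those channels is attenuated by (1 − d)² — the
  multiplicative-attenuation model of event-related desynchronization;
- **background**: independent per-channel Gaussian noise with a 1/f^α
  spectrum (α = `noise_exponent`, default 1).

Defaults (mu 12 µV, beta 6 µV at 10/20 Hz; noise RMS 3 µV; `erd_depth`
0.4) were chosen once so that the rhythm dominates its own frequency bins
(making injected attenuation measurable to within a few percent) while the
decoder search lands in the accuracy range a cooperative novice BCI user
produces; the strong-effect condition used in end-to-end checks (depth 0.7
on C3/C4) is cleanly decodable by design. No single "true" effect size
exists for this participant, so these are study conditions, not estimates.

What the generator does **not** emulate: volume conduction and realistic
forward mixing, ocular/muscular artifacts, nonstationary drift, electrode
impedance changes across sessions. Passing tests therefore demonstrate the
correctness of the pipeline's algorithms and bookkeeping under the model's
assumptions, not clinical-grade decoding performance on real EEG.

Cue schedules are balanced shuffles (exactly n/2 per class per run), with
4-s cues and uniform 4–6-s inter-cue intervals; a 5-s lead-in precedes the
first cue and a final interval follows the last. Force traces are 1-D
signed signals (extension positive): zero-mean noise until a latency, then
a 1-s linear ramp to the peak.

## Signal chain

Offline: resample to 250 Hz (polyphase, anti-aliased), zero-phase
(forward–backward) Hamming-windowed-sinc FIR band-pass 6–35 Hz, epoch
extraction on a window grid. FIR length is three periods of the low band
edge (odd tap count), which keeps pass-band ripple well under 1 dB and
stop-band attenuation beyond 40 dB near the design edges. Online: the same
design applied causally at 1–45 Hz before resampling, accepting the
filter's group delay as the real system would.

The analysis-window grid is start ∈ {0.5, 1.0, 1.5, 2.0, 2.5, 3.0} s with a
fixed 2-s length: six placements, so that 6 windows × 9 feature–classifier
combinations = 54 candidate models. The alternative reading (windows fully
inside [0.5, 3] s, i.e. two placements) is inconsistent with that count and
was rejected.

## Features

- **Band power**: 17 equal-width sub-bands spanning 6–32 Hz (~1.53 Hz
  each), channel-averaged, log-transformed. The source material fixes only
  the dimension (17) and band; the equal-width, channel-averaged
  construction is this package's documented choice and is configurable.
- **CSP**: per-epoch trace-normalized covariances averaged within class;
  filters are generalized eigenvectors of (C₁, C₁ + C₂) with a ridge of
  1e-8 · trace/channels on the composite; 3 filter pairs from the two ends
  of the eigenspectrum (6 features); features are log normalized variances.
  The two class-wise eigenvalues of each filter sum to 1 by construction.
- **FBCSP**: CSP fitted independently inside 6–15, 15–25 and 25–32 Hz and
  concatenated (18 features). Mutual-information filter selection from the
  full filter-bank literature is deliberately not implemented — the band
  set is fixed at three.

## Model search and cross-validation

The grid is features × classifiers × windows = 54 candidates. "10 × 10"
cross-validation is interpreted as 10 repetitions of reshuffled stratified
10-fold CV. CSP/FBCSP filters are refitted inside every training fold; the
per-epoch covariances (which do not depend on labels) are precomputed once
per candidate so the per-fold work is an 8 × 8 eigendecomposition.

The third searched classifier is an ℓ2-regularized logistic regression
(REGLOG); together with LDA and a linear SVM it completes the 9
feature–classifier combinations. For SVM/REGLOG the regularization value is
chosen on an inner stratified 5-fold inside each outer training fold over
the grid 2⁻¹⁵ … 2¹⁰ (26 values, ties to the smaller value), so
hyperparameters never enlarge the 54-entry leaderboard. Because that is
~10⁵ tiny model fits, the inner path is evaluated with a damped-Newton
solver (warm-started along increasing C) that minimizes the same objectives
as the deployed estimators — C·Σ log(1 + e^(−y f)) + ½‖w‖² and
C·Σ max(0, 1 − y f)² + ½‖w‖², intercept unpenalized; a unit test pins its
solutions to scikit-learn's to ~1e-3. Outer-fold and final models are
always scikit-learn fits (LDA `lsqr`, `LinearSVC`, `LogisticRegression`).

Scores are calibrated to [−1, 1] with imagery positive: P(imagery) −
P(rest) = tanh(d/2) for the probabilistic models (d the linear decision
value, i.e. the log-odds) and tanh(d) for the SVM margin — a common scale
compatible with a 0.1 activity threshold.

Ties in CV accuracy are broken by earlier window, simpler feature
(CSP < BP < FBCSP), smaller hyperparameter, then classifier order
(LDA < SVM < REGLOG) as a final determinism key. The whole search is
deterministic under a fixed seed.

## Online chain

One raw score per 500 ms on the trailing 2-s buffer (the buffer equals the
training window so train/test features are congruent). No decision is
emitted before a full buffer exists, so a stream of duration D yields
⌊(D − 2)/0.5⌋ + 1 decisions; the 8-point moving average is undefined (and
cannot trigger) until 8 decisions exist. The smoothing buffer is reset at
each trial start.

Threshold calibration: the nominal threshold is 0.1; if the maximum raw
rest output over a ≥ 30-s eyes-open stream exceeds it, the threshold is
raised to max + 0.02, preserving "higher than the maximum rest output" in
all cases (and making false positives on the calibration stream impossible
by construction). A maximum rest output ≥ 0.98 leaves no headroom for
imagery scores and is rejected as an unusable model.

## BF control

A checkpoint passes when every enabled modality is satisfied within the
10-s timeout; each condition latches once achieved and the latency is the
first time both hold. The force condition is a crossing of a directional
threshold (default 10% of the trace's absolute range) sustained for 200 ms
— the source material specifies neither, so both are configurable. A
timed-out checkpoint marks the trial unsuccessful and the device completes
the movement passively; remaining checkpoints still run, so the limb always
receives the full cycle (the alternative — aborting the trial — is equally
consistent with the protocol text; continuing was chosen because the
passive fallback exists precisely to deliver the movement).

Levels: warm-up 1 (fully passive; excluded from success-rate denominators),
warm-up 2 (BCI-only), warm-up 3 and levels 1–3 (full BF control; level 2's
bilateral bucket task is modelled with the instrumented paretic-side
checkpoint chain only). Level 3 chains four checkpoints with FES events:
stimulation on at the grasp checkpoint with release after a 3-s wait, and
automatic switch-off after 5 s in warm-up hand trials. Sessions guarantee
at least 10 delivered repetitions by appending passive movements. Trials
per session are a parameter (the protocol text fixes only the warm-up
counts), and weekly summaries report mean ± sample SD of daily rates.

## Brain symmetry index

Squared magnitudes of the FFT of the trailing T = 4 s window (0.25-Hz
grid), averaged over each hemisphere's channel set, then the mean over
in-band frequencies of |R − L| / (R + L). The frequency band is not fixed
by the source material; the default is the 6–32 Hz feature band with a
1–25 Hz preset available. Hemisphere maps default to 10-20 label parity
(odd left, even right, midline excluded), pairing each odd-numbered site
with its even homolog; explicit maps are supported, and which channels the
original study averaged is unknown — m is whatever the map provides.
Frequencies with zero total power are skipped with k reduced.

## Outcome statistics

- Timed-task averages include 120-s caps and exclude strength tasks (lbs,
  kg).
- Percent improvement uses the mean of the three baseline assessments
  (rounded to integer percent). This convention reproduces the published
  96% and 89% exactly; a single-session baseline option exists. The
  "28%" quoted for the hand-to-table task computes to 27% under this
  convention (26% under the third-session convention) — the implementation
  reports what it computes.
- The log model y = a + b·ln(x) is least squares on (ln x, y); r is the
  correlation of data with fit, signed by the slope; the "linear
  hypothesis test" is the slope F-test, F = r²(n−2)/(1−r²) on (1, n−2) df,
  two-sided.
- Pearson p uses the t-transform t = r√(n−2)/√(1−r²) with n−2 df,
  two-sided.
- Spearman p for 3 ≤ n ≤ 8 tie-free samples is exact: the fraction of all
  n! rank permutations with |ρ| ≥ |ρ_obs| (at n = 5: ρ = 1 → 2/120 =
  0.0167; ρ = 0.3 → 82/120 = 0.6833). Ties in exact mode raise; larger n
  falls back to the t-approximation, flagged in the result.

## Problem sizes and determinism

End-to-end checks use 100 epochs (5 runs × 20 cues) of 8-channel EEG
simulated directly at the 250-Hz analysis rate, the full 54-candidate
grid, and 50 seeds for null-calibration checks; unit tests use smaller
reduced-CV configurations. A single master seed fans out to per-stage
child seeds, and identical seed + configuration reproduces bit-identical
recordings, leaderboards, models and session logs.

## Known limitations

- The synthetic forward model is rank-1 per rhythm with unit gains; CSP
  patterns on it are far cleaner than on real EEG, so saturated CV
  accuracies under strong injected ERD say nothing about clinical
  performance.
- EDF files are read (via mne) but not written; the native on-disk format
  is a TSV matrix with a JSON sidecar.
- The average-WMFT-time reduction quoted for the original study ("12%,
  11.17 s") cannot be reconstructed from the published per-task table,
  because tasks never completed in any session were omitted from it; the
  package computes averages only over the tasks it is given.
- The original study's success-rate tables depend on one participant's
  ability and are not reproduction targets; the control module's accounting
  is instead validated against brute-force recounts and an independence
  closed form.
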