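# Methods

## What is simulated

The package models a closed-set speech-on-speech recognition experiment. A
male target talker utters a five-word matrix sentence (Name, Verb, Number,
Color, Object; ten alternatives per slot) whose Name is a fixed cue word.
One, two, or four masker talkers utter sentences of identical syntax
simultaneously. The listener must report the target's Number and Color
keywords. The speech-recognition threshold (SRT) is the SNR at which both
keywords are reported correctly on half of trials, measured adaptively.
Conditions cross masker sex relative to the target (S same, D different),
masker count (TD/TS, TDD/TSS/TSD, TSSDD), and masker intelligibility
(time-forward vs per-word time-reversed maskers).

Two populations of real-world objects are replaced by synthetic models:

1. the recorded word corpus → a parametric harmonic-complex corpus;
2. the human listeners → logistic psychometric observers.

Everything between those two — word selection and exclusion, reversal,
duration matching, SNR mixing, the glimpsing statistic, the staircase, the
contrast arithmetic — is implemented exactly as the experimental protocol
specifies and is the part whose correctness the test suite pins down.

## Synthetic corpus

Each word token is a sum of harmonics of the talker's fundamental:
`x(t) = Σ_k a_k sin(2π k f0 t + φ_k)`, with `k f0 ≤ 5 kHz` and at most 20
harmonics. The amplitudes `a_k` follow a 1/k spectral tilt shaped by three
seeded Gaussian resonance peaks (centers 300–3200 Hz) standing in for
formants, so words are mutually distinguishable and talkers are separated
chiefly by F0 — the primary acoustic correlate of talker sex used here
(talker means 106 Hz target; 97/128 Hz male and 157/190 Hz female maskers;
per-word seeded jitter ±3% so the talker mean is a mean).

The amplitude envelope is deliberately **asymmetric**: a 10-ms raised-cosine
attack, an exponential decay to 25–40% of peak amplitude by word end, and a
10-ms release. Natural stressed monosyllables have this fast-rise/slow-fall
shape, and it is what makes time reversal acoustically consequential: a
reversed word ramps up slowly and ends abruptly, so reversed maskers leave
word onsets relatively exposed. With a symmetric envelope, forward and
reversed maskers would be statistically indistinguishable to any
envelope-based analysis and the intelligibility contrast would have no
energetic component at all.

Word durations are drawn uniformly from 0.3–0.5 s per (category, word) and
shared across talkers up to a seeded ±10% per-talker jitter. This range is a
stand-in chosen for plausible monosyllable durations, not a measured value.
Sharing the base duration across talkers means target and masker word slots
roughly align in time, as they do when sentences of the same syntax are
duration-matched — which is what gives reversal its onset-exposing effect at
the sentence level.

All tokens are RMS-normalized to 0.05 linear full scale (headroom for a
target plus four maskers without clipping at unit full scale). Sample rate
defaults to 22.05 kHz; speech bandwidth does not require more. Determinism:
every token's seed is an SHA-256 hash of (master seed, talker, category,
word index), so any token is reproducible in isolation and the corpus is a
pure function of its config and master seed.

What the generator does **not** emulate: phonetic content, formant
transitions, amplitude modulation within words, prosody, or any lexical
property. Consequently the simulation carries **no informational masking**:
time reversal here changes only envelope statistics, whereas for human
listeners it also removes lexical interference. Passing tests therefore
validate the apparatus and the energetic-masking direction of effects, not
the magnitudes of human masking release.

## Stimulus construction

Target specs fix the Name slot to the cue word and draw the other four slots
uniformly. Masker specs draw, per category, sequentially without replacement
from the words not used by the target or previously drawn maskers, so all
sentences in a trial use pairwise-distinct words in every category (the
exclusion applies to the Name category too).

Masker sentences are duration-matched to the target by a single global
ratio: each word is re-rendered from its synthesis parameters at the scaled
length, with pitch parameters untouched — pitch-preserving time scaling by
construction. Word boundaries are assigned by cumulative rounding so the
output length equals the target's sample count exactly. Words are reversed
before duration matching, mirroring the generation order of the protocol.
Loaded (non-parametric) audio cannot be time-scaled by this mechanism and
raises an error unless an external scaler is supplied.

Mixing: maskers are summed sample-wise; the sum is scaled so the
target-to-summed-masker long-term RMS ratio equals the commanded SNR; the
whole mixture is then rescaled to the presentation level. Levels are
dimensionless linear RMS throughout — the original 65 dB presentation level
exists in software only as the configurable level constant; no SPL
calibration is attempted. SNR is defined over the entire sentence (long-term
RMS), never framewise.

For the single-slot conditions (TD, TS, TSD) the concrete masker talker of
the required sex is picked uniformly when the condition is instantiated and
then held fixed, emulating a stable masker voice within a test run; TSS,
TDD and TSSDD use all talkers of the required sex.

## Glimpsing analysis

Envelopes are computed as sliding RMS over left-aligned full 300-ms windows
hopped every 20 ms (`floor((L−W)/H)+1` frames; no partial windows, which
avoids edge bias at the cost of ~300 ms of trailing context). A frame is a
glimpse when target RMS **strictly** exceeds combined-masker RMS; ties are
not glimpses. The mean glimpsing SNR averages `20·log10(target/masker)` in
dB over glimpsed frames — averaging dB rather than linear ratios, the more
natural reading of "averaged SNRs"; with no glimpsed frame the result is an
explicit `None`, never a sentinel value. The computation is broadband
(single-band); a multiband spectro-temporal variant is out of scope.

Scaling both components by the overall level factor cancels in the ratio, so
the analysis is applied to the mixture-scaled components; at 0 dB SNR the
scaled and unscaled conventions coincide up to that common factor.

## Simulated listeners

Per-keyword correctness is logistic in SNR with midpoint θ, spread s, guess
floor γ = 0.1 (ten alternatives) and lapse λ (default 0). Both keywords are
assumed independent, so P(both) = p², with floor 0.01. Independence is a
modeling choice — human keyword errors within a trial are likely positively
correlated — made because no trial-level human data exist to fit a
correlation. The logistic (rather than cumulative-normal) form was chosen
for closed-form inversion of P(both) = p, which supplies the analytic ground
truth for staircase validation. A demonstration device can couple θ to a
condition's mean glimpsing SNR (θ = θ₀ − g·glimpseSNR), which reproduces the
qualitative orderings (reversed easier than forward) without claiming any
fit to human data.

## Staircase

1-up/1-down on the both-keywords event: correct lowers the SNR, incorrect
raises it. Initial SNR +10 dB; step 4 dB, reduced to 2 dB for every step
commanded after the second reversal has been logged. A reversal is logged at
the trial whose response flips the commanded direction, and the reversal SNR
is the SNR presented at that trial — the standard convention, pinned by a
hand-simulated trace oracle in the tests (deterministic responder correct
iff SNR ≥ 0 yields the SNR path 10, 6, 2, −2, 2, 0, −2, 0, … and SRT
−1.0 dB). Runs last exactly 20 trials (no early stopping is specified);
validity requires ≥6 reversals, the SRT averages the last six reversal SNRs,
and invalid runs are discarded and rerun. SNR is clamped to ±(−60, +40) dB
as pure software protection; clamped runs are flagged but not discarded.
This asymmetric-event track converges on the 50% point of the *tracked*
(both-correct) function, which lies above the per-keyword midpoint — the
tests check both the convergence and the distinction.

At deep thresholds (θ ≈ −20 dB) the track carries a small positive bias
(≈0.45 dB at slope 2): the fixed +10 dB start and the 20-trial budget leave
the last six reversals slightly shy of full convergence, and discarding
sparse-reversal runs selects against the slowest descents. The bias is a
property of the procedure itself at these settings, stays within 0.5 dB
across the tested profile grid, and is shared by any implementation of the
same rules.

## Experiment simulation and contrasts

A simulated experiment crosses listeners × conditions × reversal, randomizes
condition order per listener, draws 2–3 valid runs per cell (uniformly), and
draws fresh target and masker word selections on every trial. Responses
depend on SNR only through the psychometric function, so per-trial audio is
not rendered during simulation (the word draws are still made and seeded;
any drawn trial can be rendered on demand) — rendering ~10⁴ sentences would
dominate runtime without affecting a single response.

Contrast orientation is fixed so conventional signs emerge: masking release
due to intelligibility = forward − reversed; due to sex cues = same −
different; multi-masker penalty = more − fewer. Group means pool TS/TD
(1 talker), TDD/TSD/TSS (2), TSSDD (4). TMR accounting converts each SRT by
+10·log₁₀(n maskers) before differencing, so each doubling contrast gains
exactly 10·log₁₀ 2 ≈ 3.01 dB over its SNR counterpart — an identity the
summary table reproduces to machine precision. Descriptive means and
standard errors only; with a single listener the SE is reported as NaN.
Inferential statistics (repeated-measures ANOVA and friends) are standard
library calls, not part of this package's contribution, and are omitted.

## Problem sizes and numerical choices

The shipped checks run at desk scale: 100 glimpsing trials per condition and
reversal state for the directional comparison, 10⁴ staircase replicates per
listener profile for parameter recovery (a single run is ~0.3 ms), 1000
trials per condition for the word-exclusion audit, and panels of 6–10
simulated listeners for end-to-end runs. Mixing accuracy is exact to
floating-point; the SNR assertion tolerance of 0.01 dB is bookkeeping, not a
numerical limit. Sliding RMS uses a cumulative-sum-of-squares formulation
(O(L) per signal) verified against a naive per-frame loop to 1e−12.

## Known limitations

- No informational masking: synthetic maskers carry no lexical content, so
  human-scale masking-release magnitudes cannot and should not be
  reproduced, only the energetic-masking directions.
- Harmonic-complex words are fully voiced and stationary in pitch; no
  consonants, no F0 contours.
- Keyword independence overstates the information in two keywords if human
  errors are correlated.
- The TMR correction assumes equal-level, mutually incoherent maskers;
  synthetic voices at distinct F0s satisfy this to within ~1 dB per trial
  and exactly in expectation.
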