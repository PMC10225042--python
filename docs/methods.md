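# Methods

This note documents the models, conventions, and numerical choices behind
`tussilab`, and what its synthetic data can and cannot establish.

## Segmentation

A recording is assumed pre-split to a single maneuver plus silent margins.
The trimming rule operates on a per-frame mean-square energy contour in dB
relative to the contour maximum, and keeps the span from the first through
the last frame whose level is *strictly* greater than −30 dB (equality
excluded; the maximum frame is at 0 dB, so the rule always selects at least
one frame). Boundary semantics are frame-aligned and half-open: the onset
is the first sample of the first qualifying frame, the offset one past the
last sample of the last qualifying frame.

Choices left open by the trimming rule itself:

- **Contour definition.** The energy contour uses 10 ms non-overlapping
  frames by default — the simplest contour consistent with a per-frame dB
  threshold rule. Frame length and hop are configurable
  (`RunConfig.seg_frame_s`); a different envelope (e.g. the 20 ms analysis
  contour) can be substituted by passing an explicit contour to
  `auto_trim`.
- **Partial final frame.** The trailing frame shorter than one frame
  length is kept as its own frame: maneuver offsets decay gradually and a
  dropped tail frame would bias the offset early.
- The trimmed segment is divided by its RMS so the mean squared sample is
  one. Normalization removes pre-amplifier gain and microphone-distance
  effects; absolute intensity is out of scope (it requires calibrated
  sound-level metering, not a digital recording).

Multi-maneuver bout splitting is deliberately not implemented; inputs are
one maneuver per file.

## Temporal contours

All three contours use 20 ms frames with a 10 ms hop by default. On a
0.3 s maneuver this yields ≈ 30 frames, enough for three DCT coefficients
to be meaningful; both parameters are configurable. Frames start at time
zero every hop; the trailing partial frames keep their true length.

**Amplitude** is the frame mean square (not RMS or peak): under energy
normalization the duration-weighted contour average is then exactly one,
making the amplitude average uninformative by construction and the
slope/curvature pure shape descriptors.

**Sample entropy** uses the canonical parameters m = 2, r = 0.2 × frame
SD. Frames are decimated (with anti-alias filtering) from the recording
rate to ≈ 4410 Hz before template matching; this bounds the O(n²) match
count at ~90 samples per 20 ms frame and acts as a crude low-pass focus on
the oscillation-vs-turbulence distinction. The tolerance r is computed
from the SD of the decimated frame actually matched. Both template-length
counts use starts 0..n−m−1 with self-matches excluded (Chebyshev
distance). Degenerate cases: a constant frame returns 0 (perfect
predictability); if either match count is zero, the frame is flagged
undefined. SampEn is only *statistically* non-increasing in r: at very
small tolerances match counts are sparse and the estimate is noisy, so the
monotonicity property is documented (and tested) for r ≥ 0.3 × SD.

**Kurtosis** is Pearson (non-excess) kurtosis m₄/m₂² with 1/n central
moments, anchoring a Gaussian frame at 3 and a full-period sinusoid at
1.5. (The folk anchor "uniform ↦ 0" sometimes quoted for this statistic is
incorrect — a uniform histogram has Pearson kurtosis 1.8 — so only the
Gaussian anchor is asserted anywhere.) Zero-variance frames are undefined.

**Shape descriptors.** Undefined frames are dropped (never imputed) before
fitting; at least three defined values are required. With x_n the retained
contour and N its length:

    average   = (1/N) Σ x_n
    slope     = (2/N) Σ x_n cos(π (n+½) · 1/N)
    curvature = (2/N) Σ x_n cos(π (n+½) · 2/N)

The first basis function falls from +1 to −1 over the contour, so a
*decreasing* contour has *positive* slope; the second is positive at the
ends and negative in the middle, so a *convex* (downward–upward) contour
has *positive* curvature. The 2/N scaling makes coefficients comparable
across contour lengths; the average is the plain mean. Linearity and the
time-reversal symmetry (slope negates, average/curvature invariant) follow
from the DCT-II basis and are property-tested.

## Spectral decomposition

One orthonormal DCT-II is taken over the whole segment (the features
describe the maneuver as a unit, not a frame sequence). Coefficient k maps
to frequency f_k = k·f_s/(2N); coefficients are partitioned into the five
half-open bands [0,400), [400,800), [800,1600), [1600,3200), [3200, f_s/2)
Hz, an edge frequency going to the higher band. Each band's constituent is
the inverse DCT of its coefficients with all others zeroed, so the
constituents sum to the segment exactly and, by Parseval (orthonormal
scaling), band coefficient energies partition the signal energy. The
implicit even (mirrored) extension of the DCT avoids the wrap-around
artifact a DFT would create by juxtaposing the decayed offset with the
abrupt onset; the equivalence with symmetric-bin filtering of the mirrored
FFT is verified in the tests. Reconstruction within 1e-9 relative L2 error
is asserted on every pipeline run, not just in tests.

Band frequency counts *unidirectional* zero crossings — transitions from a
negative sample to a non-negative one (zeros count as non-negative) — per
second, which equals f for a sinusoid at f. An all-zero or crossing-free
constituent reports 0 Hz; its (zero) energy contributes nothing to the
weighted frequency, so no NaNs propagate. The weighted frequency
Σ E_b·f_b is a five-point approximation of the spectral centroid and for
any two-tone signal lies between the tone frequencies.

## Synthetic maneuvers

The generator emulates the qualitative acoustic structure that
distinguishes the three classes, not vocal-tract physics:

- **voluntary cough** (0.39 s default): 70 ms broadband burst with a sharp
  (2 ms) attack plus a sub-800 Hz oscillation during the burst; exponential
  decaying band-noise frication (400–3000 Hz); a voiced coda (150 Hz plus
  one harmonic, raised-cosine envelope) with probability 0.5.
- **throat clearing** (0.46 s): weak short onset; one sustained ~180 Hz
  oscillation, amplitude-modulated at ~18–30 Hz, under a rise-then-fall
  (hann-squared) body envelope, plus low-level band noise.
- **reflexive cough** (0.31 s): a 10 ms high-gain pulse (5× the other
  fragments) and bursty 800–8000 Hz frication whose amplitude is modulated
  by rectified slow noise, making frame histograms heavy-tailed.

Band-shaping of all noise reuses the tested DCT filter bank. Default
durations follow the typical class lengths; gains and spectral extents
were chosen once so the class caricatures have the documented contour
shapes (convex vs concave amplitude, kurtosis ordering, high-band energy
ordering) with clear margins, and are not calibration dials. Cohorts add
lognormal per-subject random effects (σ = 0.15 on gain and duration) and
smaller per-token jitter (σ = 0.05), giving compact median CIs and a
within-subject duration correlation exceeding the between-subject one.
Reflexive tokens alternate the two induction-method labels *within* each
subject, so the urge-vs-suppressed contrast is an exact null at the token
level. All randomness flows from a single `SeedSequence` (PCG64), so
cohorts are bit-reproducible by seed across platforms.

What passing end-to-end tests therefore shows: the pipeline recovers, at
cohort scale and through the full trim → contour → DCT → rank-test chain,
exactly the feature directions the generator encodes. What it does not
show: that real coughs have those directions, that effect sizes are
realistic, or that the features separate clinical populations. Real
recordings also contain room acoustics, breath noise, device responses and
inter-token variability the generator does not model. The skin-contact
channel is a zero-phase 8th-order Butterworth low-pass at 1500 Hz — a
caricature of tissue attenuation that reproduces only its dominant effect,
the loss of high-frequency energy (and hence a lower weighted frequency).

## Group statistics

- Quartiles: linear interpolation of order statistics (type 7).
- Median CIs: percentile bootstrap, B = 2000, resampling tokens, seeded.
- Wilcoxon signed-rank: zero differences dropped, tied absolute
  differences mid-ranked; for n ≤ 25 retained pairs the p-value is exact
  over all 2ⁿ sign assignments via the shift algorithm on doubled ranks
  (doubling keeps mid-ranks integral); otherwise a normal approximation
  with tie variance correction and a 0.5 continuity correction. Statistic
  reported: W⁺.
- Mann–Whitney U: exact over all C(n₁+n₂, n₁) labelings (dynamic program
  over rank sums) when n₁+n₂ ≤ 20 and the pooled sample is tie-free;
  otherwise the tie/continuity-corrected normal approximation. Exact and
  approximate p agree within 0.01 at the boundary sizes.
- Two-sided exact p = min(1, 2·min(P(S ≤ s), P(S ≥ s))), the observed
  point mass counted in both tails (matches the standard exact
  convention).
- Tests are run at the token level, mirroring a design in which repeated
  tokens per subject enter as observations. Token-level testing ignores
  within-subject clustering and can overstate significance for paired
  class contrasts; this is a fidelity choice, not a recommendation —
  clustered or mixed-effects inference is explicitly out of scope.
- Raw p-values per feature, flagged at α = 0.05; no multiple-testing
  correction.
- A feature constant across both groups is reported with p = 1 by
  `compare_groups` (the paired test itself raises on all-zero
  differences).

## Problem sizes

The test suite and the acceptance script size their computations as
follows: filter-bank exactness over 1000 random segments of 128–3000
samples; sample-entropy oracle agreement on frames of 20–300 samples
(where O(n²) enumeration is fast); rank-test null rejection rates over
1000 replicates at n = 30 (paired) and 25 + 25 (independent); the
end-to-end cohort at the study scale of 40 subjects × 5 tokens per class
at 44.1 kHz; and the null-contrast fraction pooled over 8 replicate
cohorts of 10 subjects × 4 reflexive tokens, so the reported
non-significant fraction is an average over 120 feature-level tests rather
than a single-cohort draw.

## Known limitations

- No absolute intensity (dB SPL) — requires external calibrated metering.
- No automatic bout splitting; one maneuver per input file is assumed.
- Token-level inference ignores subject clustering (see above).
- The synthetic generator is a caricature; conclusions about real cough
  acoustics require real recordings.
- Sample-entropy values depend on the decimation target and r; contours
  computed with different settings are not comparable across runs.
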