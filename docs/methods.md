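# Methods

This note documents the models, the pinned numerical choices, and the
design decisions behind `crossaffect`, in the order of the pipeline.

## Acoustic low-level descriptors

All audio is downmixed to mono and resampled to 16 kHz so the auditory
filterbank spans 0–8 kHz.  Two frame grids share the same 10 ms hop:

* **25 ms Hamming windows** for spectral/cepstral/energy contours
  (`n_fft = 512`);
* **60 ms windows**, centered on the same frame centers, for F0 and voice
  quality (pitch periods down to 55 Hz need more than one cycle per
  window).

The 64 descriptor columns are: 4 energy-related (auditory loudness,
RASTA-filtered loudness, RMS energy, zero-crossing rate), 55 spectral
(26 RASTA-filtered auditory bands, MFCC 1–14, band energies 250–650 Hz and
1–4 kHz, roll-off points at 25/50/75/90 %, flux, centroid, entropy, slope,
psychoacoustic sharpness, harmonicity, spectral variance/skewness/
kurtosis) and 5 voicing-related (F0, log HNR, local and delta jitter,
local shimmer).  The voicing *probability* contour is computed as well but
serves as the auxiliary array defining the voiced mask rather than as a
summarized descriptor column; this is how the package reconciles the
descriptor inventory with the fixed 64-column contract.

Numerical choices:

* **Auditory spectrum / loudness.** 26 triangular Mel-spaced filters on the
  power spectrum; loudness is the sum over bands of
  `(w_b · E_b)^0.33` where `w_b` is a RASTA-PLP-style equal-loudness
  weight at the band center — a perceptual weighting plus Stevens-style
  compression.  Band energies are floored so silence gives exactly 0.
* **RASTA filtering.** The classic band-pass `0.1·(2+z⁻¹−z⁻³−2z⁻⁴)`
  numerator with a 0.94 pole is applied to each log-band trajectory over
  time; a constant trajectory settles to 0 (no DC gain).  The 26 band LLD
  columns are these filtered log trajectories.
* **Spectral statistics** use the normalized *power* spectrum as the
  probability distribution (centroid, entropy, central moments), which
  makes a pure tone a point mass: its centroid is within one FFT bin of
  the tone frequency.  Flux is the L2 distance between consecutive
  normalized power spectra (0 for the first frame).  The all-zero spectrum
  maps to 0 for centroid/roll-off/slope/entropy by convention.
* **Sharpness** is a Zwicker-style high-frequency-weighted specific-
  loudness centroid on the Bark-transformed band centers (unit weight up
  to 14 Bark, exponential emphasis above).  **Harmonicity** is the real-
  cepstrum peak in the plausible pitch quefrency range; since gain only
  shifts quefrency zero, it is gain-invariant.
* **F0** uses subharmonic summation: candidate frequencies on a
  24-per-octave grid over 55–600 Hz score `Σ_h 0.84^(h−1)·|S(h·f)|` with
  harmonics up to 5 kHz; scores are normalized by the score a spectrally
  flat frame would achieve, so the best-candidate ratio R is ≈1 for noise
  and ≫1 for harmonic frames.  Voicing probability is `R/(R+6)`,
  thresholded at 0.45 (both configurable); frames below an RMS gate of
  1e-4 are unvoiced.  A Viterbi pass with a quadratic octave-jump penalty
  smooths the candidate path; unvoiced frames report F0 = 0.
* **Voice quality.** Cycle peaks are picked once per clip
  (`scipy.signal.find_peaks` with a distance constraint from the highest
  voiced pitch) and refined to sub-sample precision by parabolic
  interpolation — without the refinement, integer-sample quantization
  would floor jitter near 1 % even for perfectly periodic signals.
  Jitter = mean |ΔT|/mean T over the cycles inside each 60 ms window
  (delta jitter on second differences, shimmer on refined peak
  amplitudes); frames with fewer than 3 periods report 0.  HNR uses the
  unbiased normalized autocorrelation at the pitch lag,
  `10·log10(r/(1−r))`, clamped to [−20, 60] dB.

All outputs are finite for arbitrary finite input (log floors, clamps),
and extraction is deterministic.

## Functionals and the 6373-dimensional manifest

The functional bank has six families.  Applied to every LLD contour *and*
its delta contour (35 functionals): percentiles (quartiles, three IQRs,
1 %/99 % percentiles, 1–99 % range), moments (arithmetic and root-
quadratic mean, SD, skewness, kurtosis), temporal shape (min/max
positions, range, contour centroid, flatness, relative durations above
25/50/75/90 % of range, rising fraction, positive-curvature fraction,
segment-length statistics) and order-5 linear prediction (gain +
5 coefficients).  Applied to the LLD contour only (19): the peaks block,
linear/quadratic regression fits, and the fraction of non-zero frames.

Deltas are first-order regression deltas with 2-frame symmetric context
and edge replication; a ramp of slope m per frame has interior delta m.

The composed space must count exactly 6373 dimensions.  The shared bank
alone gives 64 × (2·35 + 19) = 5696; the manifest reaches the documented
total by additionally applying the peaks block to the delta contours of
the 59 energy+spectral LLDs (peak structure of descriptor *change* — e.g.
delta-loudness peak distances, a musically meaningful rhythm cue) and the
regression block to the delta contours of the 4 energy LLDs:
64·89 + 59·11 + 4·7 = 6373.  The manifest
(`build_feature_index`, exportable as JSON) records for every dimension
its LLD, LLD group (prosodic/spectral/cepstral/sound quality), functional,
family and delta flag, so every feature is traceable and group shares are
well defined.  This bookkeeping is the package's own pinned convention,
chosen so the documented dimensionality, the two-block functional split
and the 64-descriptor inventory are all satisfied simultaneously.

Conventions where the functional definitions were open: a *peak* is a
local maximum above the contour mean (plateau ties go to the earliest
frame); *minima* are the mirror image below the mean; rising/falling
slopes are the positive/negative consecutive-frame differences; *segments*
are maximal runs above min + 0.25·range; *flatness* is the geometric/
arithmetic mean ratio of |x|+ε; the *contour centroid* is the time
centroid of the min-shifted contour (0.5 for constant contours);
regression time is normalized to [0, 1] so offsets are duration-invariant.
Constant contours produce the analytically forced values (mean = c,
SD = 0, slopes = 0, peak block = 0), with float-noise SDs snapped to 0.

## Gold standard (EWE)

Five-point ratings {−2…2} are mapped linearly onto {−1, −0.5, 0, 0.5, 1};
continuous ratings pass through.  Rater confidence is the Pearson
correlation of the rater's column with the across-rater mean column (the
plain mean, not leave-one-out); degenerate raters get confidence 0 with a
warning.  Negative confidences are clamped to 0 before normalization so
the EWE stays inside the convex hull of the ratings; missing ratings drop
the rater instance-wise with per-instance weight renormalization; if no
rater has positive confidence the fusion fails loudly.

A caveat established by population simulation (and reflected in the test
design): the EWE's correlation weights are not precision weights, so with
*extremely* heterogeneous raters (noise SDs 0.1/0.3/0.6) the fused rating
can track the latent truth slightly worse than the single best rater.
Under moderately heterogeneous raters (SDs 0.3–0.7) fusion beats the best
rater by ≈0.07 correlation in population, which is the regime the fusion-
quality test exercises.

## Relevance and the CDCC

The pairwise CDCC is implemented as `(|r_i+r_j| − |r_i−r_j|)/2`, which
equals the sign-consistent minimum `sign(r_i·r_j)·min(|r_i|,|r_j|)` — the
form forced by the statistic's stated range and symmetry.  The J-domain
version is the mean of the pairwise values, `(1/(J(J−1)))·Σ_{i<j}
(|r_i+r_j| − |r_i−r_j|)`, and reduces to the pairwise form at J = 2.
Significance uses `t = r·sqrt((n−2)/(1−r²))`, two-sided, Bonferroni-
multiplied by the feature count and capped at 1; star levels 0.05/0.01/
0.001 are configurable.  Top-k selection sorts descending with ties broken
by manifest order; the single-domain analog applies the pairwise CDCC to a
seeded random 50 % split of one corpus.  Group shares compare a subset's
LLD-group and functional-family composition to the full-manifest baseline;
"enriched" means the subset share exceeds the baseline share.

## Regression

Linear ε-SVR (sklearn's libsvm/SMO backend; sum-loss C formulation, as in
the analysis this package re-implements) with C = 10⁻⁵, ε = 0.1, solver
tolerance 1e-3, all configurable.  At such a small C the solution
direction is essentially a robust correlation direction — most training
points sit outside the ε tube at bound, so w ≈ C·Σ sign(y_i − b)·x_i —
which is why Pearson-r evaluation is meaningful even though the raw
prediction spread is tiny, and why duplicating the training set leaves the
*direction* of w (and hence every reported correlation) unchanged while
scaling its magnitude.

Every database is normalized with its own per-feature mean/SD
(unsupervised, so a test database never borrows training statistics);
zero-SD features map to 0.  Within-domain performance is twofold CV on
seeded random halves with the Pearson r of the *pooled* predictions,
where each fold's predictions are mean-centered before pooling: at small
C the within-fold prediction spread is far smaller than the between-fold
offset difference, which would otherwise dominate the pooled correlation.
Cross-domain cells train on the full row domain and test on the full
column domain; the task-specific condition uses the domain pair's own
CDCC² top-200, the generic condition one CDCC³ top-200 for all cells.
Grid row/column/grand means are always recomputed from the cells.

## Synthetic corpora

The generator emulates the *statistical structure* the analysis assumes,
not naturalistic speech or music.  Each clip is a harmonic complex
(8 harmonics, 1/h amplitudes, random phases) mixed with white noise at
the set noisiness ν (powers (1−ν)/ν, so HNR ≈ 10·log10((1−ν)/ν)),
amplitude-modulated at the "tempo" rate (depth 0.8), shaped by a flat,
ramp or parabolic loudness contour, and scaled to the loudness level in
dB.  Latent arousal/valence are linear combinations of the standardized
drivers plus Gaussian noise (defaults: arousal 0.55·loudness +
0.45·tempo + 0.25·F0; valence −0.45·loudness − 0.35·noisiness, with the
valence weights inverted in the "music" domain to reproduce the inverse-
valence phenomenon), rescaled to SD 0.35 and clipped to [−1, 1].
Simulated raters add independent Gaussian noise (default SDs 0.10–0.50,
K = 6) and may discretize to five points at thresholds ±0.6/±0.2.
Default durations: 2–4 s for sound/speech, 20–30 s for the music-like
mode (a scaled stand-in for full tracks).  The latent truth is stored
separately and is never visible to any pipeline stage; only evaluation
harnesses read it.

What passing the synthetic tests does **not** show: robustness to
phonetic/musical structure, reverberation, channel effects, rater biases
that are systematic rather than independent-noise, or unbalanced affect
distributions — the generator's raters are unbiased and its drivers are
exactly the cues the features measure.

### Problem sizes used by the test suite

The 5-seed recovery experiment uses 3 domains × 200 clips with 2–4 s
sound/speech clips and 4–6 s music clips — large enough that correlation
sampling error (≈1/√200) is well below the tested margins, while a full
run stays at desk scale.  Null controls use feature-level datasets
(d = 150–6373, n = 120–400) where the relevant null bands (3/√n, binomial
3.5σ on group shares) are explicit.

## Known limitations

* The DSP definitions are self-contained re-implementations of the
  documented descriptor inventory; no binary compatibility with any
  existing extractor is claimed or sought.
* The SHS pitch tracker is tuned for clean-to-moderately-noisy harmonic
  material; creaky or polyphonic inputs will produce octave ambiguities
  that the Viterbi pass only partially resolves.
* CDCC-based selection uses the test domain's own annotations when
  ranking features for a domain pair — selection is part of the analysis
  design, not a deployable zero-knowledge transfer protocol.
* With C = 10⁻⁵ the SVR is effectively scale-free; absolute prediction
  error is not meaningful and only correlations are reported.
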