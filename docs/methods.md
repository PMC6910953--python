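# Methods

This note documents the modelling choices behind `phonogroup`: what each
stage computes, which parameters matter, what the synthetic generator does
and does not emulate, and the numerical decisions that were genuinely open.

## Front-end

Audio is peak-normalised per utterance and, if sampled above 16 kHz,
anti-alias filtered and polyphase-resampled down (`scipy.signal.
resample_poly` with its default Kaiser design). Sources below 16 kHz are
rejected rather than upsampled. Frames are 15 ms with 50 % overlap
(240/120 samples) under a Hamming window; for a signal of `n` samples the
frame count is `floor((n − 240)/120) + 1` and frame *i* is stamped with its
centre time `i·7.5 ms + 7.5 ms`.

The spectral representation is the classic perceptual linear prediction
chain: FFT power spectrum → trapezoidal critical-band integration on the
Bark scale (`6·asinh(f/600)`, 21 bands at 16 kHz) → optional RASTA
filtering — band-pass `0.1·(2,1,0,−1,−2)/(1 − 0.94 z⁻¹)` applied to each
band's log-energy trajectory, with the first four output frames zeroed
while the filter warms up — → equal-loudness weighting at the band centres
→ cube-root intensity-loudness compression → inverse DFT of the
symmetrised auditory spectrum → order-*F* autoregressive fit
(Levinson-Durbin) → cepstral recursion.

Open choices, and how they were resolved:

* **Static dimension.** The static vector is c₁..c_F with c₀ (the energy
  term) excluded, so the full vector is exactly 3*F* wide after Δ and ΔΔ.
  A useful corollary: because c₀ is dropped, the cepstra are invariant to a
  constant gain even without RASTA (a gain scales the AR model's gain term
  only, not its coefficients). RASTA additionally suppresses *slowly
  varying* spectral modulation (channel drift), which a plain gain check
  cannot distinguish; the test suite therefore asserts level invariance in
  steady state and separately that RASTA changes the features of
  amplitude-modulated noise.
* **Derivatives.** "5 FIR coefficients" is read as the standard length-5
  linear-regression filter, taps `k/10` for `k = −2..2`, applied with edge
  replication so N is preserved; ΔΔ is the same filter applied to Δ.
* **Normalisation** is per-utterance peak amplitude only; no cepstral mean
  or variance normalisation is applied anywhere.
* **Numerical safety.** The Levinson recursion floors the prediction error
  at `1e-14·max(r₀, 1)` so that near-perfectly-predictable frames (pure
  tones) cannot divide by zero; the log of band energies is taken after
  adding `1e-20`.

The chain is verified against an independently coded oracle (explicit
loops, Toeplitz solve for the AR fit, dense FFT-of-log-spectrum for the
cepstrum) to 1e-6 per cell.

## Phonemic grouping

Alignments are read from Praat TextGrid (long format, tier "phones" or the
first interval tier) or CTM. The default phone → manner table follows the
standard Spanish manner-of-articulation categorisation: plosives
{p t k b d g}, fricatives {f θ s ʂ x ʝ β ð ɣ}, affricate {tʃ}, liquids
{l ʎ ɾ r ř}, nasals {m n ɲ ŋ}, vowels {a e i o u} plus glides {j w};
silence and unmapped labels fall to `other` (with a logged warning). Two
deliberate, user-overridable calls: glides pattern with vowels, and the
spirantized approximants [β ð ɣ] are classed by their *surface* manner
(fricative) rather than their canonical phoneme (plosive), since grouping
operates on acoustic segments.

A frame belongs to the segment whose half-open interval `[start, end)`
contains its centre time, tested with a 1 ns guard shifted equally on both
edges. This makes the per-class frame subsets an exact partition of every
aligned utterance (including `other`), which the suite asserts over random
tiling alignments. No rule is claimed for how a human annotator would
assign 50 %-overlapped boundary frames; centre-time membership is simply
the unambiguous convention.

## GMM-UBM

Diagonal-covariance mixtures throughout. EM initialisation is seeded
k-means++ on a ≤10 000-row subsample (deterministic fallback to a seeded
row sample when there are fewer distinct rows than components); variances
start at the global per-dimension variance and are floored at
`max(1e-3 · global variance, 1e-10)` every iteration; training stops after
25 iterations or a relative log-likelihood change below 1e-6. The
per-iteration total log-likelihood is recorded and asserted non-decreasing
(1e-8 relative slack for floor effects).

MAP adaptation is the Reynolds speaker-verification recipe with relevance
factor *r* = 16 and, by default, **means only** (weights and variances can
be enabled; they renormalise / refloor respectively). Zero adaptation
frames return the UBM unchanged, and every adapted mean coordinate provably
lies between the UBM mean and the posterior-weighted data mean. *r* and
the adapted-parameter set are not prescribed by the methodology this
package implements; the defaults are the standard practice the methodology
cites.

## Scoring and calibration

Utterance score: mean per-frame log-density under each class model
(log-sum-exp, overflow-safe to |x| = 1e6), decision statistic their
difference. Utterances left with zero frames after grouping raise
`UnscorableUtterance` and are excluded from metrics (counted in logs).
The threshold λ is placed at the EER point of the *training-fold* utterance
scores: candidate thresholds are the midpoints of the open intervals
between consecutive distinct pooled scores (plus the two unbounded ends);
the interval minimising |FPR − FNR| wins, ties broken towards smaller
total error and then towards the widest contiguous run of minimisers, and
λ is that interval's midpoint. Mathematically tied error differences are
merged under a 1e-12 float guard (class-count rationals can differ in the
last ulp). A score exactly at λ is called control ("strictly higher"
semantics). Speaker-level scores are the mean of the speaker's utterance
log-likelihood ratios; the aggregation is a package choice, emitted
alongside utterance-level results.

## Fusion and metrics

Fusion is an L2-regularised logistic regression (lbfgs, penalty strength
1/C = 1e-4 — small and fixed, only there to keep collinear or constant
score components well-posed) fit on training speakers' score tuples; the
fused score is the linear predictor. Only scores sharing (F, G) are ever
combined. Metrics: accuracy in percent with a 95 % Wald binomial
half-width `1.96·√(p̂(1−p̂)/n)·100` (Wilson can be substituted by the
user), AUC as the rank-based Mann-Whitney statistic with ties counted ½,
sensitivity and specificity with PD positive.

## Experiments

Cross-validation is speaker-level, class-stratified and seeded (11 folds
by default). Per fold: class models are MAP-adapted on training speakers
only, λ is calibrated on training-fold scores only, and decisions are
pooled across folds into a single confusion matrix per grid cell (more
stable than averaging fold accuracies when folds hold 1–2 speakers per
class; both speaker- and utterance-level tables are emitted).
Cross-corpora validation adapts on two corpora jointly (speaker ids
prefixed by corpus to stay globally unique), calibrates λ on the pooled
adaptation scores, and tests on the held-out third; only the approaches
with ungrouped adaptation (baseline, `phon_raw`) are eligible since the
test corpus may lack alignments. Best-cell reporting follows the grid-max
convention (accuracy, then AUC, then smaller G, then smaller F) — an
optimistic selection, flagged as such.

## Synthetic corpora: what a green test establishes

Feature mode draws each segment's frames from a per-manner-class diagonal
Gaussian (fixed class means drawn once from a package-constant stream,
unit emission std) plus a per-speaker offset (σ = 0.3 per dimension, the
between-speaker variability that makes speaker-disjoint evaluation
non-trivial). The patient effect adds `shift · σ_emission` to the mean
and scales the variance of the targeted classes only — an idealised,
exactly known analogue of spirantization/vowel-centralisation, *not* a
model of real dysarthric acoustics. Default material is a read-sentence
grammar containing all five speech manner classes (a DDK "pa-ta-ka"
grammar is also provided); durations are uniform within stated ranges;
segment boundaries sit halfway between frame centres so alignments and
frame selection agree exactly. Defaults (20 + 20 speakers, 4 utterances
each, D = 30 i.e. nominal F = 10) mirror the scale of small clinical
corpora.

Waveform mode renders the same segment plans as crude source-filter audio
(formant-filtered pulse trains, shaped noise, closure + burst) to exercise
the full front-end; its patient effect (noise-filled closures, attenuated
bursts) is qualitative only.

Consequently a green end-to-end test establishes that the pipeline detects
a localised distributional difference through the correct grouping and not
through others — it says nothing about clinical accuracy on real speech.

One behaviour of the stated world deserves a note: with *no* effect in the
grouped frames, accuracies can fall systematically *below* chance (e.g.
~20 % rather than ~50 %). This is the leave-one-out anti-correlation of
random speaker effects: the held-out speaker's offset is absent from its
own class's adaptation data but its negation is (slightly) present in the
class mean of the remaining speakers, biasing the likelihood ratio against
the true class. It is a property of speaker-disjoint evaluation on small
corpora with speaker variability and no class signal, not a defect of the
implementation; the null-hypothesis acceptance check therefore uses a
fully null corpus with the ungrouped baseline, where the bias is diluted
across all frames.

## Known limitations

* No voice-activity detection, pitch features, or feature normalisation
  beyond amplitude peak normalisation.
* The forced aligner itself is out of scope: alignments are consumed, not
  produced.
* The EER threshold, MAP hyper-parameters and EM schedule are standard
  choices, not fitted to any clinical data; absolute accuracies on real
  corpora are expected to depend on them.
* Waveform-mode synthesis is deliberately minimal; conclusions about the
  front-end's behaviour on real speech should not be drawn from it.
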