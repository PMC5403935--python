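# Methods

## Problem and data model

The unit of analysis is the *phrase*: a human-annotated melodic unit of a
monophonic song. Melodies are grouped into *tune families* (variants of the
same tune); a phrase's *stability* is the fraction of its family's other
variants in which the phrase can be found. The package models notes as
(onset, duration, MIDI pitch) with rational time in quarter-note units —
rational, because phrase-equality (the repetition predictor) compares onsets
exactly, and floating-point onsets would make exact equality fragile. Pitch
spelling, key, and meter are deliberately not represented: every quantity
computed downstream consults only pitch and onset. Families carry a role
label (`training`: carries occurrence annotations for threshold calibration;
`test`: feeds the stability analysis; `background`: trains the expectancy
model), mirroring the three-way corpus split such analyses use.

Corpora are read from a JSON schema (rationals as `[numerator, denominator]`
pairs, round-trip exact) or from monophonic Humdrum \*\*kern with phrase
marks. The kern reader merges ties into single notes and drops rests (the
predictors are defined on notes; a rest only advances time). It trusts the
encoded phrase marks and performs no segmentation of its own.

## Occurrence detection

Whether phrase *q* (n notes) occurs in melody *s* is decided by three
similarity measures with complementary invariances:

* **City-block** — the best contiguous length-n window: score
  −min_w (1/n)Σ|pitch(qᵢ) − pitch(wᵢ)|; −∞ if the melody is shorter than
  the query. Pitch- and position-exact: no gaps, no transposition
  invariance.
* **Local alignment** — Smith–Waterman on pitch sequences with match +1,
  mismatch −1, linear gap −0.5, cells floored at 0; best cell divided by n.
  Insertion/deletion tolerant, transposition sensitive.
* **SIAM** — structure induction on (onset, pitch) point sets: for every
  translation vector carrying a query point onto a melody point, the number
  of query points landing on melody points; max count / n. Invariant under
  transposition and time shift by construction.

Each measure votes (score ≥ threshold); the default combination is majority
(2 of 3), with `all`/`any` available. The scoring constants, window scheme,
point representation and combination rule are configurable package defaults:
retrieval experiments on annotated folk-song corpora support combining
these three measure families, but no single set of constants is canonical,
so the architecture (3 measures + thresholds + combiner) is fixed and the
constants are calibratable.
`calibrate_thresholds` grid-searches per-measure thresholds (quantile-thinned
observed scores as candidates) maximizing F1 against labeled examples,
breaking ties toward higher thresholds. Detection is monotone: raising any
threshold can only switch detections off.

Stability excludes the source melody by default (a phrase trivially occurs
in itself); `include_source=True` is available since published judgement
counts are ambiguous on this point.

## The seven predictors

All interval-based predictors use **whole-melody context**: a phrase's first
notes take intervals from the end of the preceding phrase, so only a
melody's opening notes have undefined values. Undefined notes are discarded
from phrase averages; a phrase with no defined notes raises and is dropped
from the outcome table (with a logged count) rather than imputed.

* **Length** Len = n.
* **Repetition** Rep = number of phrases in the source melody whose
  (onset-from-phrase-start, pitch) point set equals the query's, counting
  the query itself (≥ 1). Note the equality ignores the duration of each
  phrase's final note — two restatements may end long vs. short.
* **Position** Pos = 1-based phrase index.
* **Proximity** Prox = −mean |pitch interval| over defined notes; defined
  for |interval| < 12 (the proximity principle makes no prediction at an
  octave or beyond). Range (−12, 0], 0 for all-repeated pitches.
* **Reversal** Rev = mean of the two-factor note score: after an
  implicative interval I and realized interval R, direction = +1 if
  |I| > 6 semitones and R changes direction (lateral R = 0 counts as a
  change), −1 if |I| > 6 and R continues, 0 for small I; return = +1.5 if R
  changes direction and lands within 2 semitones of the pre-implicative
  pitch (|I + R| ≤ 2). Note values live in {−1, 0, 1, 1.5, 2.5}; exhaustive
  enumeration over I, R ∈ [−11, 11] confirms the range [−1, 2.5] exactly.
  Treating lateral motion as a reversal is a configurable choice.
* **Surprisal** Sur = mean information content −ln P(interval | context)
  over defined notes, under the PPM model below. Natural log by
  convention here (base configurable). Equivalently the negative log
  geometric mean of the note probabilities.
* **Motif repetivity** MR, below. Range [−1, 0].

## PPM expectancy model

A variable-order Prediction-by-Partial-Matching model over pitch-interval
symbols, trained on the background corpus: counts of all interval n-grams up
to length 9 (mean phrase length in notes ⇒ contexts of up to 8 intervals)
per melody, never crossing melody boundaries. The model is long-term only:
frozen after training, never updated by query material.

Prediction uses interpolated smoothing with escape method C and no
exclusion: at each order the maximum-likelihood estimate
count/(total + distinct) is blended with the next-shorter context via escape
mass distinct/(total + distinct), bottoming out in a uniform order −1
distribution over |alphabet| + 1 symbols, so any unseen symbol keeps
positive probability and the distribution over alphabet ∪ {novel} sums to
one (unit-tested to 1e-9 against a literal recursion oracle). Update
exclusion and short-term/combined variants are deliberately out of scope.
Models serialize to plain-JSON count tables, reload bit-exactly.

## Motif entropy and repetivity

Consecutive note pairs are coded as M-type symbols: a signed, quality-blind
interval class (same; step 1–2; third 3–4; fourth 5; tritone 6; fifth 7;
sixth 8–9; seventh 10–11; octave+ ≥ 12) crossed with a duration-ratio class
(successor/predecessor note-duration ratio; "equal" band [0.8, 1.25], else
shorter/longer). The class tables and band are configurable constants. A
motif of l notes is a window of l − 1 symbols; a phrase of n notes yields
n − l + 1 motifs of length l.

For each l ∈ {2..6}, normalized entropy H(l) = −Σ f log₂ f / log₂ N over
the motif relative frequencies f, N the total motif count; H = 1 iff all
motifs are distinct, 0 iff one motif covers the phrase. Lengths with ≤ 1
motif are skipped (no repetition is measurable), and
MR = −mean of H(l) over contributing lengths. The normalization uses the
same total-count N in both the frequencies and the log₂ N denominator —
this is what produces the exact H = 1 ceiling.

The duration class is computed from note durations rather than
inter-onset intervals: a phrase of n notes needs n − 1 symbols, and the
last note has no following onset; within phrases on the synthetic duration
grid the two coincide.

## Outcome table and the mixed model

Occurrence records (one per phrase × sibling variant) join per-phrase
features; standardization statistics (mean, SD) are computed over *unique
phrases* and broadcast to rows, since the published feature distributions
are phrase-level. The model is a logistic GLMM with fixed slopes for the
seven standardized features and a random intercept per tune family, which
absorbs the family-dependent error of the detector:

logit P(occurs) = β₀ + βᵀF + u_tf,  u_tf ~ N(0, σ²_tf).

**Estimation.** Maximum likelihood. The marginal likelihood integrates one
scalar random effect per family; optimization uses the Laplace
approximation, with the per-family modes found by a Newton iteration
vectorized across families and warm-started between objective evaluations,
and L-BFGS-B over (β, log σ) with a projected-gradient tolerance of 1e-6
(σ bounded in [1e-4, 25]; at the lower bound the fit coincides with plain
logistic regression to 1e-3, which is unit-tested against statsmodels).
At the optimum the reported log-likelihood is refined by 20-node adaptive
Gauss–Hermite quadrature centered and scaled at each family's mode
(`n_quad=1` restores the pure Laplace value). The refinement matters in
small-family/large-σ regimes where the Laplace error can reach ~0.1; with
it, the log-likelihood agrees with an independent quadrature oracle to
numerical precision, and with lme4's glmer to its own Laplace error. Wald
standard errors come from a central-finite-difference observed information
matrix; the SE of σ is obtained on the log scale and delta-transformed.
Non-convergence is flagged on the result, never silent.

**Model selection.** All 2⁷ subsets of the predictors (plus intercept-only)
are fitted and ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), with
k = slopes + intercept + 1 variance parameter and n the number of
phrase × melody rows. Non-convergent subsets are listed and excluded from
the ranking. A best-model-per-parameter-count table is available.

**Effect size.** Nakagawa–Schielzeth R² with the logit distribution-specific
variance π²/3: marginal = σ²_f/(σ²_f + σ²_tf + π²/3) with σ²_f the variance
of the fixed linear predictor over rows; conditional adds σ²_tf to the
numerator. With σ_tf = 0.84 and marginal R² = 0.05, the implied conditional
R² is 0.22 — the internal-consistency check the test suite performs.
Multicollinearity is assessed from the correlation matrix of the estimate
covariance; no multiple-testing correction is applied (the analysis reports
CIs, not corrected p-values).

## Synthetic data: what it emulates, and what it does not

**Melody level.** A tune family is a prototype melody plus variants obtained
by independent per-note mutation. The prototype draws phrase lengths from
N(9.11, 2.23²) rounded and clipped to [3, 26] (the published phrase-length
distribution), pitches from a mostly-stepwise random walk (steps of 0–2
semitones, leaps of 3–7 with probability 0.12, reflected into a singable
range), durations from a small grid, and restates an earlier phrase with
probability 0.15. Variants substitute a note's pitch (±1–2 semitones) with
probability 0.05 and insert/delete notes with probability 0.02 each,
per note, per variant. These rates are the package's standing study
conditions: at mean phrase length 9 they mutate roughly half of all phrase
copies, which yields stability values spread over [0, 1] rather than
saturating at either end. The mutation log gives each phrase copy's edit
count, so occurrence annotations (`generate_annotations`) are *lineage*
ground truth — a pair of phrase copies counts as the same phrase when their
combined edit count is ≤ 2 (about one edit per copy) — entirely independent
of the similarity measures they are used to calibrate. Calibration on these
labels reaches F1 ≈ 0.92; perfect separation is not expected, since an edit
count threshold and a similarity threshold genuinely disagree near the
boundary — similar detectors evaluated against human occurrence annotations
on real folk-song corpora also miss a substantial share (~30%) of relevant
occurrences.

What the generator does *not* emulate: tonal or metrical structure, Dutch
folk-song idiom, text underlay, or drift-based (neutral) transmission.
Passing tests therefore demonstrate pipeline correctness and calibrated
behaviour under a plausible mutation model, not musicological claims about
any real corpus.

**Feature level.** For parameter recovery the outcome table is drawn
directly from the GLMM: standardized features are i.i.d. N(0, 1) per
phrase, family intercepts N(0, σ²_tf), and each phrase contributes
`variants_per_family − 1` Bernoulli rows. Defaults are the published
estimates (β₀ = −0.22; slopes Len −0.30, Rep 0.09, Pos −0.10, Prox 0.10,
Rev 0.05, Sur −0.24, MR 0.08; σ_tf = 0.84), so the recovery experiment
doubles as a plausibility check of that model's signs and magnitudes. Raw
feature columns are emitted with the published phrase-level means/SDs.

## Problem sizes and numerical choices in the test suite

* Parameter recovery: 50 replicates of 2,000 phrases × 5 rows (10,000
  rows, 150 families); each parameter must land within 2 SE of truth in
  ≥ 90% of replicates — a per-parameter coverage criterion (2 SE is a ~95%
  interval per parameter; demanding joint coverage of all nine parameters
  at 90% would be incompatible with nominal coverage: 0.95⁹ ≈ 0.65).
* Subset-selection power: 50 replicates of 250 phrases × 5 rows (1,250
  rows, 30 families) with a single planted slope of −0.6 and σ_tf = 0.5;
  the planted feature must appear in the AICc-best model in ≥ 45 of 50.
* Similarity oracles: 200 random instances with ≤ 8 query and ≤ 15 melody
  notes against exhaustive window/substring-pair/translation-vector
  brute force; PPM against a literal recursion on a 3-melody toy corpus
  (1e-9); GLMM log-likelihood against 61-node adaptive quadrature (0.1) and
  one lme4 cross-check via Rscript.
* All stochastic routines take explicit integer seeds; generators are
  bit-reproducible under a fixed seed.

## Known limitations

* The similarity constants and combination rule stand in for unpublished
  ones; absolute stability values depend on calibration quality.
* The PPM model implements one configuration (escape C, interpolated, no
  exclusion, long-term only); other IDyOM configurations would shift
  surprisal values, though typically monotonically.
* The reversal quantification is the published two-factor reduction;
  treatment of unisons and octave-plus implicative intervals follows the
  stated rules rather than any unpublished table.
* Laplace optimization with quadrature-refined likelihood is accurate for
  the family sizes used here, but fits with very small families and large
  σ_tf inherit the usual Laplace parameter bias; increase `n_quad`-based
  refits if that regime matters.
* The kern reader covers the monophonic subset of Humdrum needed here, not
  the full standard (no spine splits, no chords, no editorial signifiers
  beyond those stripped).
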