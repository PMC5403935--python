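# melostab

Phrase stability and memorability in folk-song tune families.

Folk songs transmitted orally survive as groups of variants of the same tune
(*tune families*). Some melody phrases resist change — they recur almost
verbatim across variants — while others mutate freely. `melostab`
operationalizes a phrase's **stability** as its frequency of occurrence
across the other variants of its tune family, and asks whether stability is
predictable from properties tied to melody recall.

The pipeline has three stages:

1. **Occurrence detection.** A query phrase *q* is compared against every
   melody *s* of its tune family with three similarity measures on pitch
   sequences — windowed city-block distance, Smith–Waterman local alignment,
   and SIAM point-set structure induction on (onset, pitch) pairs — each with
   a threshold, combined by (default) majority vote. Thresholds can be
   calibrated by F1 grid search against annotated examples.
2. **Memorability predictors.** Seven per-phrase features: phrase length
   *Len* (number of notes), phrase repetition *Rep* (exact restatements
   within the source melody), phrase position *Pos* (serial index), average
   pitch proximity *Prox* and average pitch reversal *Rev* (Schellenberg's
   two-factor quantification of Narmour's implication–realization expectancy
   model), surprisal *Sur* (mean information content under a variable-order
   PPM model of pitch intervals trained on a background corpus), and motif
   repetivity *MR* (negated mean normalized entropy of FANTASTIC-style
   motif distributions for motif lengths 2–6).
3. **Stability model.** With binary outcomes y (phrase occurs in a variant
   or not) and standardized features F, a logistic mixed model with a random
   intercept per tune family:

   logit P(y = 1) = β₀ + βᵀF + u_tf,  u_tf ~ N(0, σ²_tf)

   fitted by maximum likelihood (Laplace optimization, adaptive Gauss–Hermite
   refined log-likelihood), with all-subsets model selection by AICc and
   effect sizes as Nakagawa–Schielzeth marginal/conditional R².

Real corpora enter through Humdrum \*\*kern files (monophonic, phrase-marked)
or a documented JSON melody schema; a two-tier synthetic generator (mutated
tune families at the melody level; outcome tables drawn straight from the
logistic model at the feature level) exercises every stage.

## Worked example

```python
from melostab import (FamilyGenConfig, generate_corpus, train_ppm,
                      compute_features, detect_occurrences, stability,
                      build_outcome_table, fit_glmm, r2_nakagawa, aicc)
from melostab.pipeline import occurrences_to_frame
from melostab.synthetic import generate_annotations
from melostab.occurrence import calibrate_thresholds, score_pair

# a synthetic corpus of 20 families x 6 variants, and a background corpus
cfg = FamilyGenConfig(n_families=20, variants_per_family=6,
                      repeat_probability=0.25, p_sub=0.08, p_ins=0.03, p_del=0.03)
corpus, log = generate_corpus(cfg, seed=7)
background, _ = generate_corpus(FamilyGenConfig(n_families=20), seed=8,
                                role="background")
ppm = train_ppm(background)

# calibrate detection thresholds on lineage-annotated families
annotated = [(score_pair(q, tgt), label)
             for fam in corpus.families[:6]
             for q, src, tgt, label in generate_annotations(fam, log)]
thresholds = calibrate_thresholds(annotated)

# stability of one phrase
fam = corpus.families[8]
src = fam.melodies[0]
k, m, freq = stability(src.phrases[0], src, fam, thresholds)
print(f"phrase 1 of {src.id}: occurs in {k}/{m} variants (stability {freq:.2f})")

# full pipeline: occurrences + features -> outcome table -> mixed model
records = detect_occurrences(corpus, thresholds)
table = build_outcome_table(occurrences_to_frame(records),
                            compute_features(corpus, ppm))
fit = fit_glmm(table)
print(fit.summary().round(3).to_string(index=False))
marginal, conditional = r2_nakagawa(fit)
print("sigma_tf:", round(fit.sigma_tf, 3), " AICc:", round(aicc(fit), 1))
print("R2 marginal:", round(marginal, 3), " conditional:", round(conditional, 3))
```

Output:

```
phrase 1 of TF9_v1: occurs in 5/5 variants (stability 1.00)
       parameter  estimate    se  ci_low  ci_high
       intercept     0.269 0.098   0.076    0.462
          length    -0.425 0.041  -0.505   -0.345
      repetition     0.587 0.105   0.382    0.792
        position    -0.005 0.038  -0.078    0.069
       proximity     0.108 0.058  -0.006    0.222
        reversal    -0.236 0.043  -0.320   -0.152
       surprisal    -0.047 0.056  -0.158    0.063
motif_repetivity     0.251 0.041   0.171    0.331
sigma_tf: 0.406  AICc: 4626.8
R2 marginal: 0.151  conditional: 0.192
```

Reading this: each slope is the change in log-odds of a phrase occurring in
a sibling variant per standard deviation of the predictor. Here longer
phrases are markedly less stable (−0.43) and phrases that repeat within
their melody markedly more so (+0.59) — the mutation process directly
rewards shortness and within-melody repetition — while σ_tf = 0.41 says
families differ substantially in their baseline stability. The conditional
R² (0.19) is what fixed and family effects explain together.

A `melostab` command-line tool wraps the same pipeline
(`melostab simulate families`, `detect`, `train-ppm`, `features`, `table`,
`fit`, `select`, …); run `melostab --help`.

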