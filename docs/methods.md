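# Methods

## The presence-fraction score

A lexicon maps each domain *d* to a set of terms *T_d*. A prepared document
is an ordered token sequence; a term matches iff its own token sequence
occurs contiguously in the document. The domain score is the matched
fraction |matches| / |T_d| ∈ [0, 1]. Three consequences of this definition
drive the implementation:

* **Presence, not frequency.** A term repeated fifty times counts once. This
  is forced by the defining example (2 of 10 terms present ⇒ 20%) and makes
  the score a bounded fraction rather than a length-confounded count.
* **One normalization code path.** Lexicon terms are normalized at load time
  with exactly the document normalization (NFKC, casefold, punctuation →
  space keeping word-internal apostrophes, whitespace collapse), so matching
  is string equality over token n-grams. No stemming or lemmatization: the
  score's denominator is the term list as curated, and silently conflating
  inflections would change its meaning.
* **Domains are scored independently.** Terms may overlap across domains and
  a token run can satisfy several domains; nothing in the definition couples
  them.

Scores are carried as fractions everywhere and multiplied by 100
(percentage points) only when entering a regression. With score SDs around
0.04–0.10, per-unit-fraction odds ratios would span the whole 0→1 range and
be unreadable; per-point ORs (e.g. 1.06) are the natural reporting unit.
The factor is a `scale` argument on every model function.

## Translation

Bilingual corpora are handled by translating *before* matching, behind a
`TranslationProvider` contract (pure function of its input within a run).
Shipped providers: identity (default) and a word-for-word dictionary stub.
The stub exists because translation accuracy is an external property the
pipeline must not depend on; it also powers the simulator's bilingual mode,
where a fraction of tokens is replaced by invertible synthetic foreign forms.

## Cohort conventions

* **Unit of analysis.** Regressions run at admission level; baseline tables
  at patient level, keeping each patient's chronologically first admission
  (order encoded in `admission_id`; the collapse is deterministic and
  idempotent). No within-patient clustering correction is applied — repeat
  admissions are treated as independent, with a logged warning so the choice
  is visible.
* **Length-of-stay dichotomization.** Long stay means `los_days` strictly
  greater than 3.0. A stay of exactly 3 days codes short: the 3-day
  involuntary-admission window motivating the cutoff includes its third day.
  The threshold is a parameter (default 3).

## Statistical battery

* Continuous group comparisons use one-way ANOVA (with two groups, F = t²).
  Categorical comparisons use the Pearson chi-square test of homogeneity on
  the groups × {yes, no} table without continuity correction, so identical
  groups give statistic 0 and p = 1. A literal Cochran Q (subjects ×
  treatments, matched binary data) is exposed separately for
  repeated-measures layouts; it is not the right test for independent
  groups, which is why homogeneity is the operational default.
* Post hoc pairwise t-tests are pooled-variance (Student) by default and are
  reported only for domains whose omnibus ANOVA has p < α (default 0.05).
  P-values are unadjusted for multiplicity; a Bonferroni toggle exists but
  is off by default, matching the convention of reporting raw post hoc p's.
* Logistic and Cox CIs are Wald intervals on the coefficient scale with
  exponentiated endpoints. Logistic models fit by Newton iterations to
  relative tolerance 1e-8, at most 100 iterations; non-convergence or
  separation flags the whole model (NaN estimates plus a flag string) rather
  than silently emitting garbage. Cox models handle ties by Efron's method
  and drop zero-variance covariates, flagging the model if the domain score
  itself is constant. Sex is coded female = 1; diagnosis reference level is
  depression.

## The synthetic-data generator

The generator is designed so that ground truth is *analytic*:

* **Scores.** For an admission in group *g*, each of the *m* terms of domain
  *d* is included independently with probability `p[g][d]`. The realized
  score is Binomial(m, p)/m, so E[score] = p and SD = sqrt(p(1−p)/m) — with
  the default m = 40 and p ≈ 0.08–0.19, SDs land in the observed 0.04–0.10
  range. Default `p[g][d]` values are the observed group means of the
  motivating cohort.
* **Notes.** Lexicon terms are built from synthetic token atoms unique to
  each term and disjoint from the filler vocabulary, so a term can match
  only because it was planted; notes are assembled by shuffling *units*
  (term token tuples and filler words), keeping multi-word terms contiguous.
  Consequently the pipeline score of a generated note equals the cohort's
  stored score exactly — a property the tests assert, not just approximate.
* **Outcome.** The long-stay indicator is Bernoulli(expit(β₀ + Σ β_d ·
  100·score_d + covariate terms)). Defaults plant β = log(1.06) per point on
  negative valence and log(0.95) on arousal, with intercept 0.75 (≈ 70–75%
  long stays, consistent with a mean stay near 9 days). Durations are then
  drawn from arm-specific log-normals truncated to respect the 3-day split
  (long: median 9 days, σ_log = 0.7; short: median 1.5 days, σ_log = 0.45),
  so dichotomization reproduces the drawn outcome by construction. The
  binary outcome, not the duration, carries the planted signal — mirroring a
  dichotomized primary analysis.
* **Determinism.** One global seed; every stage and every admission derives
  a substream via `SeedSequence(seed, spawn_key=(stage, index))`. The cohort
  generator and the note generator therefore realize identical per-term
  inclusion draws, and regenerating any stage in isolation is reproducible.
* **Default sizes.** 612/83/37 admissions over 465/73/33 patients (732/571
  overall); extra admissions are assigned to uniformly chosen patients of
  the same group. Demographics per group: age ~ Normal(36.4, 18.3²),
  (31.3, 15.3²), (34.8, 14.7²) clipped to 18–90; female fractions
  0.63/0.534/0.667; CCI ~ Poisson(0.3/0.1/0.1); history flags are sparse
  independent Bernoullis.

What the generator does **not** emulate: clinical language (notes are token
soup by design), Korean morphology (the bilingual mode is token
substitution), secular trends, admission clustering beyond shared patient
demographics, and any correlation between domains beyond what the outcome
model induces. Passing tests therefore validate the *pipeline and the
statistics*, not the clinical validity of any particular term list.

## Simulation studies in the test suite

Problem sizes were chosen to give the binomial error bars room inside each
acceptance band while keeping the suite quick:

* **Type-I error** (2000 replicates each): group comparisons on null cohorts
  of 150/50/30 admissions; regression Wald tests on single-group null
  cohorts of n = 600. Empirical rejection at α = 0.05 must lie in
  [0.03, 0.07] (binomial SE at 2000 reps ≈ 0.005).
* **Parameter recovery** (200 replicates): logistic OR 1.5 per point at
  n = 2000 (intercept centered so the outcome is balanced); OLS slope 0.5
  per year of age with σ = 1 at n = 500; Cox rate ratio 2 at n = 1000.
  Nominal 95% CIs must cover the truth in ≥ 90% of replicates.
* **Generator calibration**: 5000 notes at p = 0.2 through the full text
  pipeline; mean score within 3 binomial SEs of 0.2. Plus the exact default
  counts (732/571, 612/83/37).
* **Sign consistency** (100 replicates at the default study sizes): a domain
  planted to lengthen stay must give OR > 1 in the logistic model and
  discharge HR < 1 in the Cox model in ≥ 90% of replicates.

## Known limitations

* No negation or uncertainty handling: "denies insomnia" scores the arousal
  domain. This is inherent to bag-of-words presence scoring.
* Wald intervals are first-order; in small groups (the default bipolar group
  has 37 admissions against 9 parameters) the logistic model may fail to
  converge and is then flagged — expected behavior, not an error.
* ANOVA is applied to length of stay despite its skew, and post hoc p's are
  unadjusted; both are deliberate conventions of the analysis design, not
  statistical recommendations.
* The patient-baseline collapse keeps the first admission; other choices
  (last, aggregate) would give slightly different baseline tables and are
  not configurable beyond reordering `admission_id`.
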