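# Methods

This document records the models the package implements, every default
parameter and why it has its value, what the synthetic data do and do not
claim, and the numerical choices behind the estimators.

## 1. Articulatory feature space and substitution costs

`phone_features` ships two fixture tables (`src/speakvar/data/vowels.csv`,
`consonants.csv`):

- vowels: 2 features, **Height** and **Forwardness**, in [0, 1];
- consonants: 8 features, **Aspiration, Place, Constrictor, Stop, Nasal,
  Lateral, Sulcal, Double**, in [0, 1].

The distance between two same-category phonemes is the **L1 distance**
between their feature vectors. Cross-category pairs have no feature
distance; they are costed by a flat rule (below).

The shipped inventory is the transcription set used for coding learner
productions. Two entries deserve note:

- `/i/ = (1, 1)`: the source tables list six vowels without /i/, but the
  worked arithmetic requires d(/a/, /i/) = 1.5, which pins /i/ at the
  high-front corner (1, 1) given /a/ = (0, 0.5). Adding /i/ (and /u/)
  leaves the vowel category maximum unchanged at 1.5.
- ASCII aliases (`E→ε`, `tS→tʃ`, …) are applied on read so transcripts can
  be typed without IPA input.

Length distinctions are deliberately not transcribed; symbols carrying a
length mark are rejected with an error.

**Cost scheme** (`CostScheme`, all defaults):

| parameter | value | rationale |
|---|---|---|
| indel cost | 1.0 | a fully missing/spurious segment is a maximal error |
| within-category substitution | `L1 / category_max × 0.8` | scales every same-category substitution into [0, 0.8], strictly cheaper than indels and cross-category errors |
| cross-category substitution | 1.0 | vowel↔consonant confusions are treated as maximal, like indels |
| vowel normalizer | 1.5 | maximum pairwise vowel L1 distance, recomputed by brute force from the shipped table |
| consonant normalizer | 4.25 | maximum pairwise consonant L1 distance, recomputed by brute force (attained by /l/–/tʃ/) |

`default_cost_scheme` recomputes both normalizers from the fixtures and
errors out if they drift from 1.5 / 4.25 — an edited fixture fails loudly
rather than silently rescaling every score.

## 2. Stem scoring (`edit_scoring`)

The distance between a production and its target is the minimum-cost edit
sequence under the scheme above, computed by the standard O(mn) dynamic
program. The raw distance is divided by the length of the longer string;
because every per-position cost is ≤ 1, the normalized distance lies in
[0, 1] and **accuracy = 1 − normalized distance**.

Worked example: /kam/ vs /fi/ = k→f (0.2447) + a→i (0.8) + delete m (1.0)
= 2.0447; normalized 2.0447/3 = **0.682**; accuracy **0.318**. A companion
accuracy figure of 0.328 printed alongside this example in the source
write-up is arithmetically inconsistent with 1 − 0.682; the package
follows the formula and this discrepancy is excluded from the acceptance
targets.

Conventions at the boundaries: the distance between two empty strings is
0; scoring against an empty *target* is an error (no target in the
language is empty). One optimal edit script is returned with ties broken
substitution > deletion > insertion, so scripts are reproducible; the
distance itself is tie-free.

## 3. The miniature language and affix coding (`affix_coding`)

`src/speakvar/data/language.yaml` defines 4 nouns (2 front-harmony:
ʃyvεg 'hat', sεmεtεʃ 'bin'; 2 back-harmony: dɔbɔz 'box', bɔgratʃ
'cauldron') crossed with 3 locative cases, each with a front/back suffix
pair: inessive -bεn/-bɔn, adessive -nεl/-nal, superessive -εn/-ɔn. Stems
and suffixes are mapped into the transcription inventory (no length marks,
/o/→/ɔ/-style vowel-quality folding); the adessive and superessive forms
are reconstructions from the Hungarian paradigm and the front-harmony
examples. Validation enforces: exactly 4 nouns (2 + 2 by harmony), 3
cases with one suffix per harmony, all 6 suffixes pairwise distinct.

**Three-tier coding** of a produced affix against target sentence *s*,
using normalized edit distances to all 6 suffixes:

1. *case identification* = 1 iff the minimum distance to the target case's
   two suffixes is **strictly** smaller than the minimum to the other four
   (ties = ambiguous = 0);
2. *case accuracy* = 1 iff distance 0 to either alternation of the target
   case;
3. *alternation accuracy* = 1 iff distance 0 to the harmony-correct
   alternation.

Distinct suffixes make the measures nest (3 ⇒ 2 ⇒ 1); the test suite
checks the invariant exhaustively over short productions and on simulated
data.

**Training sets.** Each participant trains on 8 of the 12 sentences under
three constraints: exactly 2 sentences per noun, every case at least
twice, all 6 alternations present. The sampler enumerates all C(12,8) =
495 subsets (36 are valid) and draws uniformly from the valid family —
exact uniformity at negligible cost.

## 4. Segmentation stimuli (`segmentation`)

Lexicon: syllables {p,t,b,d} × {a,i,u}; words *babupu, bupada, dutaba,
patubi, pidabu, tutibu*.

**Streams.** Default generation concatenates 300 tokens of each word in a
random order and removes adjacent duplicate words in a single
left-to-right sweep (a one-pass fixpoint), so realized token counts fall
slightly below 300 (~1/6 of tokens are eliminated in expectation). An
alternative mode (`resample_no_repeat`) draws the sequence token by token
with no immediate repeats, preserving exact counts, for sensitivity
checks.

**TPs.** TP(X→Y) = count(XY)/count(X), with X counted over all but the
final position so every attested unit's TPs sum to exactly 1. A bigram
that is word-internal in any word is classified as within-word even if it
also straddles boundaries (its TP pools both sources). Streams are
regenerated (bounded retries) until min within-word TP **strictly** exceeds
max cross-boundary TP; with the default lexicon the margin is typically
~0.25 vs ~0.23–0.24.

**Foils.** Candidates are all 12³ trisyllables minus the 6 words, keeping
those whose two internal bigrams are unattested anywhere in the stream
(hence TP exactly 0); 6 foils are drawn uniformly without replacement.

**Test blocks.** Each of the two blocks (familiar-voice, novel-voice)
presents all 6 × 6 = 36 word–foil pairings once, in random order with a
random within-pair order; chance performance is 18/36. In the
multiple-speaker condition the three training voices each speak 12
pairings of the familiar block.

**Speaker designs.** Four synthesized voices (`en1`, `us2`, `de1` at F0
100 Hz; `us1` at 200 Hz). Single condition: every ordered
(training, novel) voice pair occurs equally often (24 participants → each
of the 12 pairs twice). Multiple condition: each 3-voice subset occurs
equally often with the held-out voice as novel. Familiar/novel block
order is counterbalanced. For the morphology experiment (3 speakers):
single-condition participants keep one speaker for all 8 training
sentences (balanced across participants); multiple-condition participants
get a per-sentence speaker map drawn uniformly from the 3⁸ maps with ≥ 2
sentences per speaker, fixed across rounds.

**Audio export.** `export_pho` renders syllable sequences as MBROLA `.pho`
text: 278 ms per syllable (60 ms consonant + 218 ms vowel) at constant F0,
no pauses at word boundaries.

## 5. Synthetic learners (`synthetic_data`)

No human data ships with this project. The simulators exist to (a)
exercise every pipeline stage on realistically shaped tables and (b)
support parameter-recovery checks of the estimators. Their defaults are
**documented study conditions**, not fitted quantities, except where noted.

### Segmentation simulator

Per-trial correctness is Bernoulli with
`logit p = β₀ + β_cond·cond + β_spk·novel + β_ord·second + β_int·cond×novel + u_participant`,
`u ~ Normal(0, σ)`; predictors are mean-centred from the realized design
(±0.5 under balance, multiple/novel/familiar-second at +0.5). This is
exactly the model the analysis fits — a correctly specified generative
check.

Defaults: β = (0.343, 0.097, −0.439, −0.258, −0.093) — the published
fitted values for this design, so recovery checks run at empirically
plausible effect sizes — and σ = 0.5, a deliberately arbitrary documented
value (the source analysis reports no intercept SD).

### Production simulator

Per (participant, round, sentence):

- **Stem**: target expected accuracy
  `0.55 + 0.059·(round−1) − 0.020·novel + u_i` (clipped to [0.02, 0.98]),
  with `u_i ~ Normal(0, 0.05)`. The round slope and novelty penalty are
  the published linear-model estimates; the base and participant SD are
  chosen to keep accuracies mid-range. The stem string is then corrupted
  to that expected accuracy (below).
- **Affix**: one of five production kinds — exact alternation,
  wrong-harmony alternation, near miss (one feature-weighted segment
  change that matches no suffix), unrelated CVC over the language's own
  phonemes, silent — drawn from a mixture starting at
  {0.50, 0.20, 0.15, 0.10, 0.05}. The exact-production probability moves
  on the logit scale: +0.30 per round (centred) and −1.10 for novel
  items; the remaining mass is shared among the other kinds in their
  base proportions. The kinds map deterministically onto the coding
  tiers (exact → 1,1,1; wrong harmony → 1,1,0; near miss → 1,0,0 or
  0,0,0; silent → 0,0,0), making coded outputs predictable in tests.

### Stem corruption and calibration

`corrupt_string(target, expected_accuracy)` applies independent
per-position edits — substitution/deletion/insertion in proportions
0.6/0.2/0.2, substitutions drawn within category with weights
∝ exp(−feature distance) — at a noise rate chosen so the **mean scored
accuracy** matches the request. The rate→accuracy curve is estimated per
target by Monte Carlo (11 grid rates × 200 draws, fixed internal seed,
cached in memory) and inverted by linear interpolation. Requests below
the curve's floor are met exactly in expectation by mixing with the empty
production; 1.0 returns the target unchanged and 0.0 the empty string.
Calibration error is ~±0.02 in the tested range.

## 6. Statistical models (`stats_report`)

**Predictor coding.** Named binary columns are mean-centred (exactly ±0.5
when balanced); interactions (`"a:b"`) are products of the centred
columns; a constant predictor raises rather than silently dropping.

**Binomial-logit family.** Frequentist random-intercept logistic GLMMs are
not available in the installed Python stack (statsmodels offers only a
Bayesian approximation), so the marginal ML fit is implemented directly:

- the random-intercept integral per participant is evaluated by
  **adaptive Gauss–Hermite quadrature** (15 nodes) centred at each
  participant's posterior mode with its Laplace curvature; modes are
  found by vectorized Newton iterations (bincount aggregation,
  warm-started between evaluations, steps clipped to ±4, tolerance 1e-9);
- (β, log σ) is maximized by L-BFGS-B (ftol 1e-11; β bounded at ±25,
  σ ∈ [1e-4, 20]) from the pooled-logit start with σ₀ = 0.3;
- standard errors come from the inverse numerical Hessian at the optimum;
  Wald z tests give p-values;
- degenerate inputs are flagged, not raised: constant responses and
  |β| > 15 set `converged = False` with `separation:*` flags; a maximal
  random-effects request falls back to the random-intercept model and
  records the fallback.

The implementation is validated in the test suite against lme4's
`glmer(..., family = binomial, nAGQ = 25)` run through Rscript on the
same data: coefficients, SEs, log-likelihood and the intercept SD agree
to ~3 decimals. lme4 is an oracle only; the fitted values come from the
Python implementation.

**Gaussian-identity family.** Stem accuracy is fitted by ML
(`reml=False`) through statsmodels `MixedLM` with its default optimizer;
p-values use t statistics at `n_obs − n_fixed` degrees of freedom
(configurable via `df_for_t`). `maximal=True` attempts by-participant
slopes and falls back (flagged) on non-convergence.

**Model comparison and rendering.** Full models are compared to matched
random-effects-only nulls by likelihood ratio tests (χ² with df = fixed
parameter difference, clipped at 0). Logit coefficients are rendered as
`exp(β)` odds and inverse-logit accuracies — e.g. 0.343 → odds 1.41,
accuracy 58%.

## 7. Reproducibility

Every stage's generator derives from
`SeedSequence([master_seed, crc32(stage_name), index])`, so pipeline runs
are pure functions of their config: identical configs give byte-identical
CSVs, recorded per-artifact as sha256 in `manifest.json`. Derived seeds
are reduced mod 2³¹.

## 8. Numerical and testing choices

- Exact-match comparisons of edit distances use an epsilon of 1e-12
  (costs are short sums of decimal fractions, so representation noise is
  far below any real margin).
- The edit-distance acceptance check compares the package DP against an
  independently structured oracle (one shared table over all string pairs
  in length order) on **all** 1365² pairs of strings up to length 5 over a
  4-phoneme inventory (~2 minutes); the module-level suite additionally
  runs a per-pair memoized-recursion oracle exhaustively to length 3 plus
  seeded samples at lengths 4–5 and on the full inventory.
- Parameter recovery runs 100 replicates of the 48-participant design and
  requires ≥ 90% CI coverage per coefficient (nominal 95%).
- The training-set sampler is checked over 10,000 draws for constraint
  satisfaction and exact support equality with the brute-force family.

## 9. Limitations

- The synthetic learners are generative conveniences, not cognitive
  models: they do not simulate segmentation learning from the streams, or
  any speaker-normalization mechanism; condition effects appear in the
  output only because they are injected as coefficients.
- The adessive/superessive suffix forms in the shipped language file are
  paradigm reconstructions (see §3); swap in a different `language.yaml`
  via `--language`/`language_path` if other forms are required.
- The logit GLMM implements random intercepts only; maximal requests fall
  back (flagged) rather than fitting random slopes.
- `.pho` export covers the stream audio spec only (constant F0, fixed
  durations); no synthesis or playback is included.
- Gaussian-family p-values use a fixed-df t approximation rather than
  Satterthwaite/Kenward-Roger corrections.
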