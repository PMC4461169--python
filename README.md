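# speakvar

Stimulus generation, production scoring and mixed-effects analysis for a
two-experiment study of **speaker-input variability in language learning**,
plus synthetic learners that make the whole pipeline testable end to end
without human data.

The package covers both experiments of the design:

1. **Statistical word segmentation.** Learners hear a continuous stream of
   CV syllables built from six trisyllabic words; the only cue to word
   boundaries is the transitional probability (TP) between syllables, which
   is higher word-internally than across word boundaries. Speaker input is
   manipulated between participants (one synthesized voice vs. three), and
   at test each word is pitted against foils whose internal bigrams never
   occurred in the stream (TP = 0), in familiar-voice and novel-voice
   blocks. Trial-level 2AFC responses are analysed with a random-intercept
   logistic mixed model.
2. **Morphology learning.** Learners acquire a miniature language crossing
   4 container nouns (two front-harmony, two back-harmony) with 3
   Hungarian locative cases, each case realized by a vowel-harmony suffix
   pair (12 sentences; 8 trained, 4 held out). Produced stems are scored
   with an articulatory-feature-weighted Levenshtein distance, produced
   affixes with a three-tier nested coding (case identification → case
   accuracy → alternation accuracy), and the resulting trial tables are
   analysed with linear and logistic mixed models.

## The core models in brief

**Stem scoring.** Each phoneme is a point in articulatory feature space
(vowels 2-dimensional, consonants 8-dimensional, all coordinates in
[0, 1]). Substituting phoneme *a* for same-category *b* costs
`L1(a, b) / category_max × 0.8`; cross-category substitutions and
insertions/deletions cost 1. The category maxima, recomputed from the
shipped tables by brute force, are 1.5 (vowels) and 4.25 (consonants).
A production's distance to its target is the minimum-cost edit sequence
(dynamic programming), normalized by the longer string's length;
**accuracy = 1 − normalized distance**.

**Affix coding.** A produced affix gets three nested binary codes:
*case identification* (strictly closer to a suffix of the target case
than to every other case's suffixes), *case accuracy* (exactly matches
either alternation of the target case), *alternation accuracy* (exactly
matches the harmony-correct alternation). Alternation accuracy ⇒ case
accuracy ⇒ case identification, always.

**Analyses.** Binary responses: logistic mixed model with by-participant
random intercepts, maximum likelihood via adaptive Gauss–Hermite
quadrature (validated coefficient-for-coefficient against lme4's
`glmer(..., nAGQ = 25)`). Continuous stem accuracy: linear mixed model
(ML) via statsmodels. Predictors are mean-centred (±0.5 under balance) so
intercepts are grand means on the link scale; models are compared to
random-effects-only nulls by likelihood ratio tests, and logit
coefficients are rendered as odds / percent-accuracy pairs.

## Worked example

Scoring the production /kam/ against the target /fi/:

```python
>>> from speakvar import (default_feature_table, default_cost_scheme,
...                       production_accuracy)
>>> table = default_feature_table()
>>> scheme = default_cost_scheme(table)   # recomputes and checks the 1.5 / 4.25 normalizers
>>> res = production_accuracy("kam", "fi", table, scheme)
>>> round(res.raw_distance, 4), round(res.normalized_distance, 3), round(res.accuracy, 3)
(2.0447, 0.682, 0.318)
>>> res.edit_script
[('substitute', 0, 'k->f'), ('substitute', 1, 'a->i'), ('delete', 2, 'm')]
```

(k→f costs 1.3/4.25 × 0.8 = 0.2447, a→i costs 1.5/1.5 × 0.8 = 0.8,
deleting m costs 1; total 2.0447 over 3 positions.)

Coding affix productions against the front-harmony inessive target /-bεn/:

```python
>>> from speakvar import default_target_language, code_affix
>>> language = default_target_language(table)
>>> sent = language.sentence("hat", "inessive")
>>> for prod in ("bεn", "bɔn", "bεm", "nεl"):
...     print(prod, tuple(code_affix(prod, sent, language, table, scheme)))
bεn (1, 1, 1)
bɔn (1, 1, 0)
bεm (1, 0, 0)
nεl (0, 0, 0)
```

Generating one TP-controlled stream and its zero-TP foils:

```python
>>> import numpy as np
>>> from speakvar import generate_stream, generate_foils
>>> rng = np.random.default_rng(5)
>>> bundle = generate_stream(rng=rng)   # 300 tokens/word, duplicates eliminated
>>> len(bundle.word_sequence)
1493
>>> min(bundle.within_word_tps().values()) > max(bundle.cross_boundary_tps().values())
True
>>> generate_foils(bundle, 6, rng)
['badipu', 'pibata', 'bidibu', 'titupi', 'dutiba', 'tabibi']
```

## Command line

```bash
speakvar run-all --experiment exp1 --seed 7 --out results/demo   # full pipeline
speakvar gen-stimuli --seed 3 --out results/stimuli              # one stream + foils
speakvar score productions.csv scored.csv                        # stem scoring
speakvar code-affixes productions.csv coded.csv                  # affix coding
```

`run-all` also accepts a YAML config (`--config`); every run writes a
`manifest.json` with per-artifact sha256 hashes, and the same config always
produces byte-identical outputs.

## Layout

- `src/speakvar/` — the library: `phone_features`, `edit_scoring`,
  `affix_coding`, `segmentation`, `synthetic_data`, `stats_report`, `cli_io`.
- `src/speakvar/data/` — feature-table and language fixtures (CSV/YAML).
- `analysis/` — thin numbered drivers writing to `results/`.
- `scripts/acceptance.py` — standalone recomputation of the headline values.
- `docs/methods.md` — models, parameter choices, numerical details and
  limitations.
- `tests/` — module suites plus `tests/test_acceptance.py`.

## Scope

No human data ships with this project; all behavioral tables are produced
by the synthetic learners in `speakvar.synthetic_data`, whose generating
parameters are documented defaults, not empirical claims. See
`docs/methods.md` for exactly what the simulations do and do not model.
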