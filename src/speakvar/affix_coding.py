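"""The vowel-harmony target language and the three-tier affix coding.

The miniature language crosses 4 container nouns (two [-back], two [+back])
with 3 Hungarian locative cases (inessive "in", adessive "at", superessive
"on"), each case realized by a harmony-conditioned suffix pair, giving 12
sentences.  A produced affix is coded on three nested binary measures:

* case identification — 1 iff the production is strictly closer (in
  normalized weighted edit distance) to a suffix of the target case than to
  every suffix of any other case (ties count as ambiguous, hence 0);
* case accuracy — 1 iff the production exactly reproduces one of the two
  alternations of the target case (distance 0);
* alternation accuracy — 1 iff it exactly reproduces the harmony-correct
  alternation.

Because all six suffixes are pairwise distinct, the measures nest:
alternation accuracy implies case accuracy implies case identification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .edit_scoring import normalized_distance
from .phone_features import CostScheme, FeatureTable, tokenize

__all__ = [
    "Noun",
    "Case",
    "Sentence",
    "TargetLanguage",
    "AffixCodes",
    "LanguageError",
    "load_target_language",
    "default_target_language",
    "suffix_distances",
    "code_affix",
    "enumerate_valid_training_sets",
    "sample_training_set",
    "code_affix_table",
]

HARMONIES = ("front", "back")
CASE_NAMES = ("inessive", "adessive", "superessive")


class LanguageError(ValueError):
    """A target-language config violates the language's structural invariants."""


@dataclass(frozen=True)
class Noun:
    stem: tuple[str, ...]
    harmony: str
    gloss: str


@dataclass(frozen=True)
class Case:
    name: str
    suffix_by_harmony: tuple[tuple[str, tuple[str, ...]], ...]  # ((harmony, suffix), ...)

    def suffix(self, harmony: str) -> tuple[str, ...]:
        return dict(self.suffix_by_harmony)[harmony]


@dataclass(frozen=True)
class Sentence:
    noun: Noun
    case: Case
    target_suffix: tuple[str, ...]
    image_id: str
    sentence_text: str | None = None


class TargetLanguage:
    """The 4-noun x 3-case harmony language with its 12 sentences."""

    def __init__(self, nouns: Sequence[Noun], cases: Sequence[Case]) -> None:
        self.nouns = list(nouns)
        self.cases = list(cases)
        self._validate()
        self.sentences = [
            Sentence(
                noun=n,
                case=c,
                target_suffix=c.suffix(n.harmony),
                image_id=f"{n.gloss}_{c.name}",
            )
            for n in self.nouns
            for c in self.cases
        ]

    def _validate(self) -> None:
        if len(self.nouns) != 4:
            raise LanguageError(f"expected 4 nouns, got {len(self.nouns)}")
        counts = {h: sum(n.harmony == h for n in self.nouns) for h in HARMONIES}
        if counts != {"front": 2, "back": 2}:
            raise LanguageError(f"harmony imbalance: {counts}")
        if len(self.cases) != 3:
            raise LanguageError(f"expected 3 cases, got {len(self.cases)}")
        suffixes = [c.suffix(h) for c in self.cases for h in HARMONIES]
        if len(set(suffixes)) != 6:
            raise LanguageError("the 6 suffix alternations must be pairwise distinct")
        for c in self.cases:
            if set(dict(c.suffix_by_harmony)) != set(HARMONIES):
                raise LanguageError(f"case {c.name!r} must have one suffix per harmony")

    def all_suffixes(self) -> list[tuple[str, tuple[str, ...], str]]:
        """(case name, suffix, harmony) for all 6 alternations."""
        return [
            (c.name, c.suffix(h), h) for c in self.cases for h in HARMONIES
        ]

    def sentence(self, gloss: str, case_name: str) -> Sentence:
        for s in self.sentences:
            if s.noun.gloss == gloss and s.case.name == case_name:
                return s
        raise LanguageError(f"no sentence for ({gloss!r}, {case_name!r})")


@dataclass(frozen=True)
class AffixCodes:
    """The three nested binary codes for one produced affix."""

    case_identification: int
    case_accuracy: int
    alternation_accuracy: int

    def __iter__(self):
        yield self.case_identification
        yield self.case_accuracy
        yield self.alternation_accuracy


def load_target_language(path, table: FeatureTable) -> TargetLanguage:
    """Load and validate a language config (YAML or JSON).

    The config lists the nouns with their harmony class and each case's
    front/back suffix forms; transcriptions resolve against ``table``.
    """
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    raw = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    try:
        nouns = [
            Noun(tokenize(n["stem"], table), n["harmony"], n.get("gloss", n["stem"]))
            for n in raw["nouns"]
        ]
        cases = [
            Case(
                c["name"],
                (
                    ("front", tokenize(c["front_suffix"], table)),
                    ("back", tokenize(c["back_suffix"], table)),
                ),
            )
            for c in raw["cases"]
        ]
    except KeyError as exc:
        raise LanguageError(f"language config missing key: {exc}") from exc
    for n in nouns:
        if n.harmony not in HARMONIES:
            raise LanguageError(f"unknown harmony class {n.harmony!r} for {n.gloss!r}")
    return TargetLanguage(nouns, cases)


def default_target_language(table: FeatureTable) -> TargetLanguage:
    """The shipped reconstruction of the experiment's miniature language."""
    return load_target_language(resources.files("speakvar.data") / "language.yaml", table)


def suffix_distances(
    production,
    language: TargetLanguage,
    table: FeatureTable,
    scheme: CostScheme,
) -> dict[tuple[str, str], float]:
    """Normalized edit distance from a production to each of the 6 suffixes.

    Keys are (case name, harmony).  Normalized (not raw) distances are used
    so the closest-suffix ordering is well defined across suffix lengths.
    """
    prod = tokenize(production, table)
    return {
        (case_name, harmony): normalized_distance(prod, suffix, table, scheme)
        for case_name, suffix, harmony in language.all_suffixes()
    }


def code_affix(
    production,
    target_sentence: Sentence,
    language: TargetLanguage,
    table: FeatureTable,
    scheme: CostScheme,
) -> AffixCodes:
    """Code one produced affix on the three nested measures (see module docs)."""
    dists = suffix_distances(production, language, table, scheme)
    target_case = target_sentence.case.name
    own = [d for (case, _), d in dists.items() if case == target_case]
    other = [d for (case, _), d in dists.items() if case != target_case]
    eps = 1e-12
    case_id = int(min(own) < min(other) - eps)
    case_acc = int(min(own) < eps)
    alt_acc = int(dists[(target_case, target_sentence.noun.harmony)] < eps)
    return AffixCodes(case_id, case_acc, alt_acc)


# -- training-set sampling ----------------------------------------------


def _satisfies_constraints(subset: Sequence[Sentence], language: TargetLanguage) -> bool:
    noun_counts = {n.gloss: 0 for n in language.nouns}
    case_counts = {c.name: 0 for c in language.cases}
    alternations = set()
    for s in subset:
        noun_counts[s.noun.gloss] += 1
        case_counts[s.case.name] += 1
        alternations.add((s.case.name, s.noun.harmony))
    return (
        all(v == 2 for v in noun_counts.values())
        and all(v >= 2 for v in case_counts.values())
        and len(alternations) == 6
    )


def enumerate_valid_training_sets(language: TargetLanguage) -> list[tuple[int, ...]]:
    """All 8-sentence subsets (as index tuples into ``language.sentences``)
    satisfying the sampling constraints: exactly two sentences per noun,
    each case at least twice, each of the six alternations at least once."""
    valid = []
    for idx in combinations(range(len(language.sentences)), 8):
        if _satisfies_constraints([language.sentences[i] for i in idx], language):
            valid.append(idx)
    if not valid:
        raise LanguageError("no 8-sentence subset satisfies the training constraints")
    return valid


def sample_training_set(
    language: TargetLanguage, rng: np.random.Generator
) -> list[Sentence]:
    """Uniformly sample one valid 8-sentence training set.

    Enumeration of the C(12,8)=495 candidates is cheap and makes the sample
    exactly uniform over the constraint-satisfying family.
    """
    valid = enumerate_valid_training_sets(language)
    idx = valid[int(rng.integers(len(valid)))]
    return [language.sentences[i] for i in idx]


def code_affix_table(
    productions: pd.DataFrame,
    language: TargetLanguage,
    table: FeatureTable,
    scheme: CostScheme,
    *,
    production_col: str = "affix_transcription",
) -> pd.DataFrame:
    """Append the three affix-code columns to a production table.

    Rows are matched to sentences by their ``gloss`` and ``case`` columns.
    """
    out = productions.copy()
    codes = []
    for _, row in out.iterrows():
        sentence = language.sentence(row["gloss"], row["case"])
        codes.append(tuple(code_affix(row[production_col], sentence, language, table, scheme)))
    out[["case_identification", "case_accuracy", "alternation_accuracy"]] = pd.DataFrame(
        codes, index=out.index
    )
    return out
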