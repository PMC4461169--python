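"""Word-segmentation stimuli: TP-controlled streams, foils and test designs.

The segmentation experiment exposes learners to a continuous stream of CV
syllables built from six trisyllabic words; the only cue to word boundaries
is the transitional probability (TP) between syllables, which is higher
word-internally than across boundaries.  Test items contrast each word with
foils whose internal syllable bigrams never occur in the stream (TP = 0).
Speaker-input variability is manipulated by presenting training with one
voice or with three of the four synthesized voices, counterbalanced across
participants.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd

__all__ = [
    "Lexicon",
    "SpeechStreamBundle",
    "TestBlock",
    "DesignError",
    "DEFAULT_WORDS",
    "DEFAULT_VOICES",
    "generate_stream",
    "transitional_probabilities",
    "generate_foils",
    "build_test_blocks",
    "assign_speakers",
    "export_pho",
    "block_boundaries",
]

DEFAULT_CONSONANTS = ("p", "t", "b", "d")
DEFAULT_VOWELS = ("a", "i", "u")
DEFAULT_WORDS = ("babupu", "bupada", "dutaba", "patubi", "pidabu", "tutibu")

#: voice id -> constant F0 in Hz (three male diphone voices and one female)
DEFAULT_VOICES = {"en1": 100, "us2": 100, "de1": 100, "us1": 200}

#: per-syllable timing in ms: 278 total, 60 on the consonant
SYLLABLE_MS = 278
CONSONANT_MS = 60


class DesignError(ValueError):
    """A stimulus or design constraint cannot be satisfied."""


@dataclass(frozen=True)
class Lexicon:
    """A CV syllable inventory and the trisyllabic words built from it."""

    consonants: tuple[str, ...] = DEFAULT_CONSONANTS
    vowels: tuple[str, ...] = DEFAULT_VOWELS
    words: tuple[str, ...] = DEFAULT_WORDS

    @property
    def syllables(self) -> tuple[str, ...]:
        return tuple(c + v for c in self.consonants for v in self.vowels)

    def word_syllables(self, word: str) -> tuple[str, ...]:
        sylls = tuple(word[i : i + 2] for i in range(0, len(word), 2))
        unknown = set(sylls) - set(self.syllables)
        if unknown:
            raise DesignError(f"word {word!r} uses syllables outside the inventory: {unknown}")
        return sylls

    def __post_init__(self) -> None:
        for w in self.words:
            if len(w) != 6:
                raise DesignError(f"word {w!r} is not trisyllabic")
            self.word_syllables(w)

    def within_word_bigrams(self) -> set[tuple[str, str]]:
        out = set()
        for w in self.words:
            s = self.word_syllables(w)
            out.update(zip(s, s[1:]))
        return out


@dataclass
class SpeechStreamBundle:
    """A generated training stream with its boundary metadata and TP table."""

    lexicon: Lexicon
    word_sequence: list[str]
    syllable_sequence: list[str]
    boundary_index: list[int]  # syllable index at which each word starts
    tp_table: dict[tuple[str, str], float]
    token_counts: Counter
    seed_used: int | None = None

    def within_word_tps(self) -> dict[tuple[str, str], float]:
        ww = self.lexicon.within_word_bigrams()
        return {bg: tp for bg, tp in self.tp_table.items() if bg in ww}

    def cross_boundary_tps(self) -> dict[tuple[str, str], float]:
        """TPs of bigram types attested only across word boundaries.

        A bigram that is word-internal in some word is classified as
        within-word even if it also straddles boundaries; its TP pools both.
        """
        ww = self.lexicon.within_word_bigrams()
        boundary_bigrams = set()
        for k in range(1, len(self.word_sequence)):
            prev = self.lexicon.word_syllables(self.word_sequence[k - 1])
            nxt = self.lexicon.word_syllables(self.word_sequence[k])
            boundary_bigrams.add((prev[-1], nxt[0]))
        return {
            bg: self.tp_table.get(bg, 0.0) for bg in boundary_bigrams if bg not in ww
        }

    def tp_separation_holds(self) -> bool:
        within = self.within_word_tps()
        cross = self.cross_boundary_tps()
        if not within:
            return False
        return min(within.values()) > max(cross.values(), default=0.0)


def transitional_probabilities(syllable_sequence) -> dict[tuple[str, str], float]:
    """TP(X -> Y) = count(XY) / count(X), counting X over all but the final
    position so each attested unit's TPs over successors sum to exactly 1."""
    seq = list(syllable_sequence)
    if len(seq) < 2:
        raise DesignError("TP needs a sequence of at least 2 units")
    bigrams = Counter(zip(seq, seq[1:]))
    firsts = Counter(seq[:-1])
    return {(x, y): c / firsts[x] for (x, y), c in bigrams.items()}


def _eliminate_adjacent_duplicates(words: list[str]) -> list[str]:
    """Left-to-right sweep dropping any token equal to its surviving
    predecessor; a single pass reaches the fixpoint."""
    out: list[str] = []
    for w in words:
        if not out or out[-1] != w:
            out.append(w)
    return out


def generate_stream(
    lexicon: Lexicon = Lexicon(),
    tokens_per_word: int = 300,
    rng: np.random.Generator | None = None,
    *,
    mode: str = "eliminate",
    max_retries: int = 200,
) -> SpeechStreamBundle:
    """Generate one training stream and verify its TP structure.

    ``mode='eliminate'`` (the default) randomly orders ``tokens_per_word``
    tokens of each word and then removes adjacent duplicates, so
    post-elimination counts may fall below the nominal token count.
    ``mode='resample_no_repeat'`` instead draws the sequence token by token,
    never repeating the previous word, preserving exact counts (useful for
    sensitivity checks).

    The bundle is regenerated (bounded retries) until every within-word TP
    strictly exceeds every cross-boundary TP.
    """
    if len(lexicon.words) < 2:
        raise DesignError("TP separation is unsatisfiable with fewer than 2 words")
    if tokens_per_word < 1:
        raise DesignError("tokens_per_word must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()

    for attempt in range(max_retries):
        if mode == "eliminate":
            pool = [w for w in lexicon.words for _ in range(tokens_per_word)]
            order = rng.permutation(len(pool))
            words = _eliminate_adjacent_duplicates([pool[i] for i in order])
        elif mode == "resample_no_repeat":
            words = _sample_no_repeat(lexicon, tokens_per_word, rng, max_retries)
        else:
            raise DesignError(f"unknown stream mode {mode!r}")

        syllables: list[str] = []
        boundaries: list[int] = []
        for w in words:
            boundaries.append(len(syllables))
            syllables.extend(lexicon.word_syllables(w))
        bundle = SpeechStreamBundle(
            lexicon=lexicon,
            word_sequence=words,
            syllable_sequence=syllables,
            boundary_index=boundaries,
            tp_table=transitional_probabilities(syllables),
            token_counts=Counter(words),
        )
        if bundle.tp_separation_holds():
            return bundle
    raise DesignError(
        f"TP separation not achieved within {max_retries} attempts"
    )


def _sample_no_repeat(
    lexicon: Lexicon, tokens_per_word: int, rng: np.random.Generator, max_retries: int
) -> list[str]:
    words = list(lexicon.words)
    for _ in range(max_retries):
        remaining = {w: tokens_per_word for w in words}
        seq: list[str] = []
        ok = True
        while any(remaining.values()):
            options = [w for w, c in remaining.items() if c > 0 and (not seq or w != seq[-1])]
            if not options:
                ok = False
                break
            weights = np.array([remaining[w] for w in options], dtype=float)
            choice = options[int(rng.choice(len(options), p=weights / weights.sum()))]
            seq.append(choice)
            remaining[choice] -= 1
        if ok:
            return seq
    raise DesignError("could not complete a no-repeat sequence within the retry budget")


def generate_foils(
    bundle: SpeechStreamBundle,
    n_foils: int = 6,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Sample trisyllabic foils whose internal bigrams have TP 0 in the stream.

    Candidates are all trisyllables over the inventory that are not lexicon
    words and whose two internal syllable bigrams are unattested in the
    stream; the returned foils are a uniform sample without replacement.
    """
    if n_foils == 0:
        return []
    rng = rng if rng is not None else np.random.default_rng()
    attested = set(bundle.tp_table)
    candidates = []
    for s1, s2, s3 in product(bundle.lexicon.syllables, repeat=3):
        word = s1 + s2 + s3
        if word in bundle.lexicon.words:
            continue
        if (s1, s2) in attested or (s2, s3) in attested:
            continue
        candidates.append(word)
    if len(candidates) < n_foils:
        raise DesignError(
            f"only {len(candidates)} zero-TP trisyllables available, need {n_foils}"
        )
    picks = rng.choice(len(candidates), size=n_foils, replace=False)
    return [candidates[int(i)] for i in picks]


# -- test and speaker designs -------------------------------------------


@dataclass
class TestBlock:
    """One 36-trial forced-choice block with its per-trial voice plan."""

    block_kind: str  # "familiar" | "novel"
    pairs: list[dict] = field(default_factory=list)  # word, foil, word_first
    voice_plan: list[str] = field(default_factory=list)


def build_test_blocks(
    lexicon: Lexicon,
    foils: list[str],
    design_row,
    rng: np.random.Generator,
) -> tuple[TestBlock, TestBlock]:
    """Build the familiar- and novel-voice test blocks for one participant.

    Each block presents all 36 word-foil pairings once in random order with
    an independent within-pair order flip.  In the multiple-speaker
    condition the three training voices each cover 12 pairings of the
    familiar block; the novel block always uses the held-out voice.
    ``design_row`` needs fields ``condition``, ``training_voices`` and
    ``novel_voice``.
    """
    if len(lexicon.words) != 6 or len(foils) != 6:
        raise DesignError("test blocks require 6 words and 6 foils")
    training = tuple(design_row.training_voices)
    novel = design_row.novel_voice
    if novel in training:
        raise DesignError(f"novel voice {novel!r} also appears in training")
    if design_row.condition == "single" and len(training) != 1:
        raise DesignError("single condition requires exactly 1 training voice")
    if design_row.condition == "multiple" and len(training) != 3:
        raise DesignError("multiple condition requires exactly 3 training voices")

    blocks = []
    for kind in ("familiar", "novel"):
        pairings = [(w, f) for w in lexicon.words for f in foils]
        order = rng.permutation(len(pairings))
        pairs = [
            {
                "word": pairings[i][0],
                "foil": pairings[i][1],
                "word_first": bool(rng.integers(2)),
            }
            for i in order
        ]
        if kind == "novel":
            voices = [novel] * 36
        elif design_row.condition == "single":
            voices = [training[0]] * 36
        else:
            voices = [v for v in training for _ in range(12)]
            voices = [voices[i] for i in rng.permutation(36)]
        blocks.append(TestBlock(block_kind=kind, pairs=pairs, voice_plan=voices))
    return blocks[0], blocks[1]


def assign_speakers(
    experiment: str,
    condition: str,
    roster: list[str] | None = None,
    rng: np.random.Generator | None = None,
    n_participants: int | None = None,
    participant_offset: int = 0,
) -> pd.DataFrame:
    """Counterbalanced speaker assignment for either experiment.

    Segmentation experiment (``exp1``, 4-voice roster): in the single
    condition every (familiar, novel) ordered voice pair is used equally
    often (24 participants -> each of the 12 pairs twice, 6 participants
    per training voice); in the multiple condition each 3-voice subset is
    used equally often with the held-out voice as novel.  Test-block order
    is counterbalanced within condition.

    Morphology experiment (``exp2``, 3-speaker roster): single-condition
    participants get one speaker for all 8 training sentences, balanced so
    each speaker serves at least n//3 participants; multiple-condition
    participants get a per-sentence speaker map, uniform over maps with at
    least 2 sentences per speaker, fixed across rounds.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if experiment == "exp1":
        roster = roster if roster is not None else list(DEFAULT_VOICES)
        n = n_participants if n_participants is not None else 24
        return _assign_exp1(condition, roster, n, rng, participant_offset)
    if experiment == "exp2":
        roster = roster if roster is not None else ["hu1", "hu2", "hu3"]
        n = n_participants if n_participants is not None else 20
        return _assign_exp2(condition, roster, n, rng, participant_offset)
    raise DesignError(f"unknown experiment {experiment!r}")


def _balanced_bool(n: int, rng: np.random.Generator) -> list[bool]:
    half = [True] * (n // 2) + [False] * (n - n // 2)
    return [half[i] for i in rng.permutation(n)]


def _assign_exp1(
    condition: str, roster: list[str], n: int, rng: np.random.Generator, offset: int
) -> pd.DataFrame:
    k = len(roster)
    if condition == "single":
        combos = [(f, nv) for f in roster for nv in roster if nv != f]
        if n % len(combos):
            raise DesignError(
                f"single condition needs a multiple of {len(combos)} participants, got {n}"
            )
        cells = combos * (n // len(combos))
        order = rng.permutation(len(cells))
        rows = [
            {"training_voices": (cells[i][0],), "novel_voice": cells[i][1]}
            for i in order
        ]
    elif condition == "multiple":
        subsets = list(combinations(roster, k - 1))
        if n % len(subsets):
            raise DesignError(
                f"multiple condition needs a multiple of {len(subsets)} participants, got {n}"
            )
        cells = subsets * (n // len(subsets))
        order = rng.permutation(len(cells))
        rows = []
        for i in order:
            training = cells[i]
            novel = next(v for v in roster if v not in training)
            rows.append({"training_voices": tuple(training), "novel_voice": novel})
    else:
        raise DesignError(f"unknown condition {condition!r}")
    familiar_first = _balanced_bool(n, rng)
    return pd.DataFrame(
        {
            "participant": [offset + i for i in range(n)],
            "condition": condition,
            "training_voices": [r["training_voices"] for r in rows],
            "novel_voice": [r["novel_voice"] for r in rows],
            "familiar_first": familiar_first,
        }
    )


def _valid_sentence_maps(roster: list[str], n_sentences: int = 8, min_per: int = 2):
    maps = []
    for assignment in product(range(len(roster)), repeat=n_sentences):
        counts = Counter(assignment)
        if all(counts.get(i, 0) >= min_per for i in range(len(roster))):
            maps.append(tuple(roster[i] for i in assignment))
    return maps


def _assign_exp2(
    condition: str, roster: list[str], n: int, rng: np.random.Generator, offset: int
) -> pd.DataFrame:
    if condition == "single":
        base = n // len(roster)
        counts = {s: base for s in roster}
        extras = rng.permutation(len(roster))[: n - base * len(roster)]
        for i in extras:
            counts[roster[int(i)]] += 1
        pool = [s for s, c in counts.items() for _ in range(c)]
        order = rng.permutation(n)
        speakers = [tuple([pool[int(i)]] * 8) for i in order]
    elif condition == "multiple":
        valid = _valid_sentence_maps(roster)
        picks = rng.integers(len(valid), size=n)
        speakers = [valid[int(i)] for i in picks]
    else:
        raise DesignError(f"unknown condition {condition!r}")
    return pd.DataFrame(
        {
            "participant": [offset + i for i in range(n)],
            "condition": condition,
            "speakers": speakers,
        }
    )


# -- export --------------------------------------------------------------


def block_boundaries(bundle: SpeechStreamBundle, n_parts: int = 3) -> list[int]:
    """Syllable indices splitting the stream into ``n_parts`` training
    blocks, each cut snapped to the nearest word boundary."""
    total = len(bundle.syllable_sequence)
    cuts = []
    for k in range(1, n_parts):
        target = total * k / n_parts
        cuts.append(min(bundle.boundary_index, key=lambda b: abs(b - target)))
    return cuts


def export_pho(
    syllable_sequence,
    f0_hz: int,
    *,
    syllable_ms: int = SYLLABLE_MS,
    consonant_ms: int = CONSONANT_MS,
) -> str:
    """Render a syllable sequence as MBROLA ``.pho`` text at constant F0.

    Each CV syllable becomes two phone lines (consonant then vowel) whose
    durations sum to the syllable duration; no pauses are inserted at word
    boundaries, preserving the continuous stream.
    """
    vowel_ms = syllable_ms - consonant_ms
    lines = []
    for syll in syllable_sequence:
        if len(syll) != 2:
            raise DesignError(f"syllable {syll!r} is not a CV pair")
        c, v = syll[0], syll[1]
        lines.append(f"{c} {consonant_ms} 0 {f0_hz} 100 {f0_hz}")
        lines.append(f"{v} {vowel_ms} 0 {f0_hz} 100 {f0_hz}")
    return "\n".join(lines) + ("\n" if lines else "")
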