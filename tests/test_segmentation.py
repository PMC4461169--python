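"""Streams, TP structure, foils, test blocks and speaker designs."""

from collections import Counter
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from speakvar.segmentation import (
    DEFAULT_VOICES,
    DEFAULT_WORDS,
    DesignError,
    Lexicon,
    _eliminate_adjacent_duplicates,
    assign_speakers,
    block_boundaries,
    build_test_blocks,
    export_pho,
    generate_foils,
    generate_stream,
    transitional_probabilities,
)


@pytest.fixture(scope="module")
def bundle():
    return generate_stream(rng=np.random.default_rng(5))


class TestLexicon:
    def test_default_inventory(self):
        lex = Lexicon()
        assert len(lex.syllables) == 12
        assert len(lex.words) == 6
        assert lex.word_syllables("babupu") == ("ba", "bu", "pu")

    def test_bad_word_rejected(self):
        with pytest.raises(DesignError):
            Lexicon(words=("babu",))
        with pytest.raises(DesignError):
            Lexicon(words=("baxupu", "bupada"))


class TestStream:
    def test_token_counts_bounded_by_nominal(self, bundle):
        # elimination can only remove tokens
        assert set(bundle.token_counts) == set(DEFAULT_WORDS)
        for w in DEFAULT_WORDS:
            assert bundle.token_counts[w] <= 300
            # a random permutation repeats its predecessor ~1/6 of the time,
            # so ~250 of 300 tokens survive elimination
            assert bundle.token_counts[w] > 220

    def test_elimination_single_pass_is_fixpoint(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            seq = [str(x) for x in rng.integers(0, 3, size=50)]
            once = _eliminate_adjacent_duplicates(seq)
            assert _eliminate_adjacent_duplicates(once) == once
            assert all(a != b for a, b in zip(once, once[1:]))

    def test_no_adjacent_duplicate_words(self, bundle):
        ws = bundle.word_sequence
        assert all(a != b for a, b in zip(ws, ws[1:]))

    def test_boundaries_align_with_words(self, bundle):
        for b, w in zip(bundle.boundary_index, bundle.word_sequence):
            sylls = bundle.lexicon.word_syllables(w)
            assert tuple(bundle.syllable_sequence[b : b + 3]) == sylls

    def test_tp_separation_holds(self, bundle):
        assert bundle.tp_separation_holds()
        assert min(bundle.within_word_tps().values()) > max(
            bundle.cross_boundary_tps().values()
        )

    def test_determinism(self):
        a = generate_stream(rng=np.random.default_rng(123))
        b = generate_stream(rng=np.random.default_rng(123))
        assert a.word_sequence == b.word_sequence
        assert a.tp_table == b.tp_table

    def test_resample_mode_exact_counts(self):
        bundle = generate_stream(
            tokens_per_word=50, rng=np.random.default_rng(3), mode="resample_no_repeat"
        )
        assert all(v == 50 for v in bundle.token_counts.values())
        ws = bundle.word_sequence
        assert all(a != b for a, b in zip(ws, ws[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(DesignError):
            generate_stream(tokens_per_word=0)
        with pytest.raises(DesignError):
            generate_stream(mode="shuffle")


class TestTransitionalProbabilities:
    def test_rows_sum_to_one(self, bundle):
        sums = Counter()
        for (x, _), tp in bundle.tp_table.items():
            sums[x] += tp
        for x, total in sums.items():
            assert total == pytest.approx(1.0), x

    def test_hand_computed_example(self):
        # sequence A B A B A C: A->B 2/3, A->C 1/3 (final A not a source), B->A 1
        tps = transitional_probabilities(["A", "B", "A", "B", "A", "C"])
        assert tps[("A", "B")] == pytest.approx(2 / 3)
        assert tps[("A", "C")] == pytest.approx(1 / 3)
        assert tps[("B", "A")] == pytest.approx(1.0)

    def test_too_short(self):
        with pytest.raises(DesignError):
            transitional_probabilities(["A"])


class TestFoils:
    def test_zero_tp_by_independent_recount(self, bundle):
        foils = generate_foils(bundle, 6, np.random.default_rng(11))
        assert len(set(foils)) == 6
        # independent recount of bigram occurrences straight off the stream
        seq = bundle.syllable_sequence
        attested = Counter(zip(seq, seq[1:]))
        for foil in foils:
            assert foil not in DEFAULT_WORDS
            s = tuple(foil[i : i + 2] for i in range(0, 6, 2))
            assert attested[(s[0], s[1])] == 0
            assert attested[(s[1], s[2])] == 0

    def test_deterministic_and_uniform_support(self, bundle):
        a = generate_foils(bundle, 6, np.random.default_rng(4))
        b = generate_foils(bundle, 6, np.random.default_rng(4))
        assert a == b

    def test_zero_request(self, bundle):
        assert generate_foils(bundle, 0) == []

    def test_impossible_request(self, bundle):
        with pytest.raises(DesignError, match="zero-TP"):
            generate_foils(bundle, 10_000)


class TestTestBlocks:
    def _row(self, condition="single", training=("en1",), novel="us1"):
        return SimpleNamespace(
            condition=condition, training_voices=training, novel_voice=novel
        )

    def test_single_condition_blocks(self, bundle):
        foils = generate_foils(bundle, 6, np.random.default_rng(2))
        fam, nov = build_test_blocks(
            bundle.lexicon, foils, self._row(), np.random.default_rng(8)
        )
        for block in (fam, nov):
            assert len(block.pairs) == 36
            seen = {(p["word"], p["foil"]) for p in block.pairs}
            assert seen == {(w, f) for w in DEFAULT_WORDS for f in foils}
        assert fam.voice_plan == ["en1"] * 36
        assert nov.voice_plan == ["us1"] * 36

    def test_multiple_condition_voice_split(self, bundle):
        foils = generate_foils(bundle, 6, np.random.default_rng(2))
        row = self._row("multiple", ("en1", "us2", "de1"), "us1")
        fam, nov = build_test_blocks(
            bundle.lexicon, foils, row, np.random.default_rng(8)
        )
        assert Counter(fam.voice_plan) == {"en1": 12, "us2": 12, "de1": 12}
        assert set(nov.voice_plan) == {"us1"}

    def test_novel_voice_in_training_rejected(self, bundle):
        foils = generate_foils(bundle, 6, np.random.default_rng(2))
        with pytest.raises(DesignError, match="novel"):
            build_test_blocks(
                bundle.lexicon,
                foils,
                self._row(training=("us1",), novel="us1"),
                np.random.default_rng(8),
            )


class TestAssignSpeakersExp1:
    def test_single_pairs_balanced(self):
        df = assign_speakers("exp1", "single", rng=np.random.default_rng(10))
        assert len(df) == 24
        pairs = Counter(
            (row.training_voices[0], row.novel_voice) for row in df.itertuples()
        )
        assert len(pairs) == 12 and set(pairs.values()) == {2}
        trainers = Counter(row.training_voices[0] for row in df.itertuples())
        assert trainers == {v: 6 for v in DEFAULT_VOICES}

    def test_multiple_subsets_balanced(self):
        df = assign_speakers("exp1", "multiple", rng=np.random.default_rng(10))
        subsets = Counter(tuple(sorted(r.training_voices)) for r in df.itertuples())
        assert len(subsets) == 4 and set(subsets.values()) == {6}
        for r in df.itertuples():
            assert r.novel_voice not in r.training_voices
            assert len(set(r.training_voices)) == 3

    def test_block_order_counterbalanced(self):
        df = assign_speakers("exp1", "single", rng=np.random.default_rng(10))
        assert df["familiar_first"].sum() == 12

    def test_indivisible_n_rejected(self):
        with pytest.raises(DesignError, match="multiple of"):
            assign_speakers("exp1", "single", n_participants=13)

    def test_participant_offset(self):
        df = assign_speakers(
            "exp1", "multiple", rng=np.random.default_rng(1), participant_offset=24
        )
        assert df["participant"].tolist() == list(range(24, 48))


class TestAssignSpeakersExp2:
    def test_single_balanced_and_constant(self):
        df = assign_speakers("exp2", "single", rng=np.random.default_rng(2), n_participants=20)
        per_speaker = Counter(r.speakers[0] for r in df.itertuples())
        assert all(v >= 20 // 3 for v in per_speaker.values())
        for r in df.itertuples():
            assert len(set(r.speakers)) == 1 and len(r.speakers) == 8

    def test_multiple_min_two_per_speaker(self):
        df = assign_speakers(
            "exp2", "multiple", rng=np.random.default_rng(2), n_participants=50
        )
        for r in df.itertuples():
            counts = Counter(r.speakers)
            assert len(r.speakers) == 8
            assert set(counts) == {"hu1", "hu2", "hu3"}
            assert all(v >= 2 for v in counts.values())

    def test_unknown_condition(self):
        with pytest.raises(DesignError):
            assign_speakers("exp2", "paired")
        with pytest.raises(DesignError):
            assign_speakers("exp3", "single")


class TestExport:
    def test_pho_lines_and_durations(self):
        text = export_pho(["ba", "bu", "pu"], 100)
        lines = text.strip().split("\n")
        assert len(lines) == 6
        assert lines[0] == "b 60 0 100 100 100"
        assert lines[1] == "a 218 0 100 100 100"
        durations = [int(l.split()[1]) for l in lines]
        assert sum(durations) == 3 * 278

    def test_pho_f0(self):
        text = export_pho(["ba"], 200)
        for line in text.strip().split("\n"):
            parts = line.split()
            assert parts[3] == "200" and parts[5] == "200"

    def test_non_cv_rejected(self):
        with pytest.raises(DesignError):
            export_pho(["bla"], 100)

    def test_block_boundaries_on_word_starts(self, bundle):
        cuts = block_boundaries(bundle, 3)
        assert len(cuts) == 2
        starts = set(bundle.boundary_index)
        total = len(bundle.syllable_sequence)
        for k, cut in enumerate(cuts, start=1):
            assert cut in starts
            assert abs(cut - total * k / 3) <= 3
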