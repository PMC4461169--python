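#!/usr/bin/env python
"""Build the segmentation training streams and their zero-TP foil sets.

Generates 24 seeded streams from the default lexicon (300 tokens per word,
adjacent duplicates eliminated), verifies the TP separation on each, draws
6 zero-TP foils per stream, and writes per-stream summaries, the foil
lists, and one example MBROLA .pho rendering per voice.
"""

from pathlib import Path

import pandas as pd

from speakvar import generate_foils, generate_stream
from speakvar._rng import derive_rng
from speakvar.segmentation import DEFAULT_VOICES, Lexicon, export_pho

MASTER_SEED = 20_240_001
N_STREAMS = 24
OUT = Path(__file__).resolve().parent.parent / "results" / "stimuli"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    lexicon = Lexicon()
    stream_rows, foil_rows = [], []
    first_bundle = None
    for s in range(N_STREAMS):
        rng = derive_rng(MASTER_SEED, "stimuli", s)
        bundle = generate_stream(lexicon, 300, rng)
        if first_bundle is None:
            first_bundle = bundle
        foils = generate_foils(bundle, 6, rng)
        stream_rows.append(
            {
                "stream": s,
                "n_word_tokens": len(bundle.word_sequence),
                "n_syllables": len(bundle.syllable_sequence),
                "min_within_word_tp": min(bundle.within_word_tps().values()),
                "max_cross_boundary_tp": max(bundle.cross_boundary_tps().values()),
                "tp_separation_holds": bundle.tp_separation_holds(),
            }
        )
        foil_rows.extend({"stream": s, "foil": f} for f in foils)

    pd.DataFrame(stream_rows).to_csv(OUT / "streams.csv", index=False)
    pd.DataFrame(foil_rows).to_csv(OUT / "foils.csv", index=False)

    # one short .pho excerpt per voice (first 30 syllables of stream 0)
    excerpt = first_bundle.syllable_sequence[:30]
    for voice, f0 in DEFAULT_VOICES.items():
        (OUT / f"stream00_{voice}.pho").write_text(export_pho(excerpt, f0))

    print(f"wrote {N_STREAMS} stream summaries and foil lists to {OUT}")


if __name__ == "__main__":
    main()
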