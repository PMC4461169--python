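# Miniature Hungarian locative-case target language: 4 container nouns
# (2 per harmony class) x 3 cases, each case with a [-back]/[+back] suffix
# alternation. Stems and suffixes are written in the transcription inventory
# (no length distinctions; Hungarian /o/ -> /ɔ/, /a:/ -> /a/, /e:/ -> /ε/).
# The adessive and superessive surface forms are a reconstruction from
# standard Hungarian two-way harmony pairs; the inessive pair is as documented.
nouns:
  - stem: ʃyvεg
    harmony: front
    gloss: hat
  - stem: sεmεtεʃ
    harmony: front
    gloss: bin
  - stem: dɔbɔz
    harmony: back
    gloss: box
  - stem: bɔgratʃ
    harmony: back
    gloss: cauldron
cases:
  - name: inessive
    gloss: in
    front_suffix: bεn
    back_suffix: bɔn
  - name: adessive
    gloss: at
    front_suffix: nεl
    back_suffix: nal
  - name: superessive
    gloss: on
    front_suffix: εn
    back_suffix: ɔn
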