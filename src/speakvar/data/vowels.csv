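# Articulatory feature values for vowels (Connolly-style Height/Forwardness).
# /i/ is an extension of the published six-vowel table: (1,1) is the only
# assignment consistent with the documented /a/-/i/ distance of 1.5.
symbol,category,Height,Forwardness
y,vowel,1,1
ε,vowel,0.5,1
a,vowel,0,0.5
ɔ,vowel,0.5,0
u,vowel,1,0
ə,vowel,0.5,0.5
i,vowel,1,1
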