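ascii,ipa
E,ε
O,ɔ
@,ə
N,ŋ
S,ʃ
Z,ʒ
tS,tʃ
dZ,dʒ
tʃ⌢,tʃ
dʒ⌢,dʒ
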