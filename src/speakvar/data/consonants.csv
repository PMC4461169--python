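symbol,category,Aspiration,Place,Constrictor,Stop,Nasal,Lateral,Sulcal,Double
n,consonant,0,0.85,0.85,1,1,0,0,0
m,consonant,0,1,1,1,1,0,0,0
ŋ,consonant,0,0.6,0.6,1,1,0,0,0
b,consonant,0,1,1,1,0,0,0,0
p,consonant,1,1,1,1,0,0,0,0
d,consonant,0,0.85,0.85,1,0,0,0,0
t,consonant,1,0.85,0.85,1,0,0,0,0
g,consonant,0,0.6,0.6,1,0,0,0,0
k,consonant,1,0.6,0.6,1,0,0,0,0
f,consonant,0.5,0.9,1,0.9,0,0,0,0
v,consonant,0,0.9,1,0.9,0,0,0,0
s,consonant,0.5,0.85,0.85,0.9,0,0,1,0
ʃ,consonant,0.5,0.8,0.85,0.9,0,0,0.8,0
z,consonant,0,0.85,0.85,0.9,0,0,1,0
ʒ,consonant,0,0.8,0.85,0.9,0,0,0.8,0
tʃ,consonant,0.5,0.85,0.85,0.95,0,0,0.8,1
dʒ,consonant,0,0.85,0.85,0.95,0,0,0.8,1
w,consonant,0,0.8,0.8,0,0,0,0,0
l,consonant,0,0.85,0.85,0,0,1,0,0
r,consonant,0,0.8,0.85,0,0,0,0,0
j,consonant,0,0.7,0.6,0,0,0,0,0
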