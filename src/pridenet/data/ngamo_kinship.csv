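id,AS,AS4,AS5,AT1,KE,KE3,KE4,KW,NL,NR,PH
AS,1,0.5,0.5,0.25,0.25,0.125,0.125,0.25,0,0,0.25
AS4,0.5,1,0.5,0.313,0.125,0.313,0.313,0.125,0,0,0.125
AS5,0.5,0.5,1,0.313,0.125,0.313,0.313,0.125,0,0,0.125
AT1,0.25,0.313,0.313,1,0.125,0.313,0.313,0.125,0,0,0.125
KE,0.25,0.125,0.125,0.125,1,0.5,0.5,0.5,0,0,0.25
KE3,0.125,0.313,0.313,0.313,0.5,1,0.5,0.25,0,0,0.125
KE4,0.125,0.313,0.313,0.313,0.5,0.5,1,0.25,0,0,0.125
KW,0.25,0.125,0.125,0.125,0.5,0.25,0.25,1,0,0,0.25
NL,0,0,0,0,0,0,0,0,1,0.5,0
NR,0,0,0,0,0,0,0,0,0.5,1,0
PH,0.25,0.125,0.125,0.125,0.25,0.125,0.125,0.25,0,0,1
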