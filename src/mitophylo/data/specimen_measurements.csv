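index,value
BM,6.33
FL,35.87
LHB,45.10
TBL,15.11
TL,32.70
EL,13.22
EW,7.25
TRL,7.51
LHF,7.15
WL,91.67
WS,216.44
McIII,28.31
III1,10.27
III2,15.55
McIV,27.80
IV1,7.85
IV2,7.49
McV,29.55
V1,16.46
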