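# Allosterically regulated reactions of the hRBC network (literature-curated)
HK
PFK
PK
DPGM
G6PDH
PDGH
PRPPsyn
TKI
TKII
AdPRT
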