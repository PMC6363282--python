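# Currency (cofactor-load) exchange fluxes of the hRBC fixture
EX_Pi
EX_ATP
EX_ADP
EX_NAD
EX_NADH
EX_NADP
EX_NADPH
EX_H2O
EX_H
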