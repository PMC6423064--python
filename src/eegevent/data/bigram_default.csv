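,SPSW,PLED,GPED,EYEM,ARTF,BCKG
SPSW,0.40,0.00,0.00,0.10,0.20,0.30
PLED,0.00,0.90,0.00,0.00,0.05,0.05
GPED,0.00,0.00,0.60,0.00,0.20,0.20
EYEM,0.10,0.00,0.00,0.40,0.10,0.40
ARTF,0.23,0.05,0.05,0.23,0.23,0.23
BCKG,0.33,0.05,0.05,0.23,0.13,0.23
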