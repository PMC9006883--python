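gene	protein_change	count
TP53	p.R175H	812
CTNNB1	p.S45F	54
EGFR	p.A289D	2
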