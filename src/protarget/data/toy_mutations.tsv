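gene	sample_id	variant_class	protein_change
TP53	S01	stopgain	p.R213*
CTNNB1	S02	frameshift_indel	p.S45fs
TP53	S03	missense	p.R175H
CTNNB1	S04	missense	p.S45F
EGFR	S05	missense	p.A289D
ALB	S06	other	p.?
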