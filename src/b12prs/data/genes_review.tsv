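symbol	source
FUT2	review
FUT6	review
TCN1	review
TCN2	review
CUBN	review
MTRR	review
MUT	review
CD320	review
ABCD4	review
MMACHC	review
MMADHC	review
MMAA	review
MMAB	review
CBS	review
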