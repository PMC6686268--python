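# 0-based alignment-column indices of marked residue sites
label	column
H2	94
H5	207
LE1	225
LE2	226
P1	158
P2	230
P3	232
P4	264
P5	266
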