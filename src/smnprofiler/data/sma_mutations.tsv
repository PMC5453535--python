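# SMA-linked SMN1 point mutations with structural coverage discussed in the
# profiling workflow.  Positions use SMN (UniProt Q16637) author numbering, the
# same numbering the SMN-related PDB entries carry.  mut "X" marks a nonsense
# (premature stop) mutation.
# position	wt	mut	label
2	A	G	A2G
44	D	V	D44V
92	W	S	W92S
102	W	X	W102X
111	A	G	A111G
116	I	F	I116F
134	E	K	E134K
136	Q	E	Q136E
279	G	C	G279C
279	G	V	G279V
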