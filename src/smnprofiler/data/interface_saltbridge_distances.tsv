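# Published atom-pair salt-bridge distances at the SMN-Gemin2 complex
# interface (NMR ensemble 2leh): four nitrogen-oxygen pairs between SMN Asp36
# and Gemin2 His120/His123.  distance_model15 is the inter-atomic distance in
# the fifteenth structure model; distance_mean/std summarize the same pair
# over all 32 models.  Distances in Angstrom.
# id	atom_a	atom_b	distance_model15	distance_mean	distance_std
SB1	NE2,A123His	OD2,B36Asp	3.1	5.73	0.93
SB2	ND1,A123His	OD1,B36Asp	4.0	7.04	1.01
SB3	ND1,A120His	OD1,B36Asp	2.6	6.87	0.94
SB4	NE2,A120His	OD1,B36Asp	3.7	5.57	0.64
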