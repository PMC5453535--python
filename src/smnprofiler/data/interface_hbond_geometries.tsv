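# Published hydrogen-bond geometries at the SMN-Gemin2 complex interface
# (NMR ensemble 2leh, 32 models): the four interface hydrogen bonds reported
# between SMN Lys45 / Gemin2 Gln109, SMN Lys45 / Gemin2 Gln105 and
# SMN Asp36 / Gemin2 Trp124.
# kind = model  : geometry in the single structure model where the bond was
#                 detected (model column = 1-based model index)
# kind = ensemble: mean over all 32 models, with one standard deviation in the
#                 *_std columns.
# Distances in Angstrom, angle_adh in degrees (angle at the donor between the
# donor->acceptor and donor->hydrogen directions).
# id	kind	model	acceptor	donor	hydrogen	d_da	d_ha	angle_adh	d_da_std	d_ha_std	angle_adh_std
HB1	model	8	OE1,A109Gln	NZ,B45Lys	HZ1,B45Lys	2.63	1.68	18.83
HB1	ensemble	0	OE1,A109Gln	NZ,B45Lys	HZ1,B45Lys	4.11	4.13	86.43	1.30	1.41	41.56
HB2	model	8	O,A105Gln	NZ,B45Lys	HZ3,B45Lys	2.70	1.68	9.22
HB2	ensemble	0	O,A105Gln	NZ,B45Lys	HZ3,B45Lys	3.73	3.76	84.34	0.97	1.28	41.27
HB3	model	19	O,A105Gln	NZ,B45Lys	HZ2,B45Lys	2.94	2.06	26.72
HB3	ensemble	0	O,A105Gln	NZ,B45Lys	HZ2,B45Lys	3.73	3.64	76.15	0.97	1.18	33.94
HB4	model	11	OD2,B36Asp	NE1,A124Trp	HE1,A124Trp	2.76	1.95	28.37
HB4	ensemble	0	OD2,B36Asp	NE1,A124Trp	HE1,A124Trp	5.91	5.53	62.29	1.15	1.19	10.49
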