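# Expected NMR-observable side-chain nuclei per residue type, PDB v3 atom
# nomenclature: all side-chain carbons and nitrogens plus all side-chain
# hydrogens (oxygen and sulfur have no routinely assigned nuclei and are
# omitted).  Used as the default completeness reference for the chemical-shift
# assignment audit; users may restrict or extend it.
# res_type	nuclei (comma separated)
ALA	CB,HB1,HB2,HB3
ARG	CB,CG,CD,CZ,NE,NH1,NH2,HB2,HB3,HG2,HG3,HD2,HD3,HE,HH11,HH12,HH21,HH22
ASN	CB,CG,ND2,HB2,HB3,HD21,HD22
ASP	CB,CG,HB2,HB3
CYS	CB,HB2,HB3,HG
GLN	CB,CG,CD,NE2,HB2,HB3,HG2,HG3,HE21,HE22
GLU	CB,CG,CD,HB2,HB3,HG2,HG3
GLY
HIS	CB,CG,CD2,CE1,ND1,NE2,HB2,HB3,HD1,HD2,HE1,HE2
ILE	CB,CG1,CG2,CD1,HB,HG12,HG13,HG21,HG22,HG23,HD11,HD12,HD13
LEU	CB,CG,CD1,CD2,HB2,HB3,HG,HD11,HD12,HD13,HD21,HD22,HD23
LYS	CB,CG,CD,CE,NZ,HB2,HB3,HG2,HG3,HD2,HD3,HE2,HE3,HZ1,HZ2,HZ3
MET	CB,CG,CE,HB2,HB3,HG2,HG3,HE1,HE2,HE3
PHE	CB,CG,CD1,CD2,CE1,CE2,CZ,HB2,HB3,HD1,HD2,HE1,HE2,HZ
PRO	CB,CG,CD,HB2,HB3,HG2,HG3,HD2,HD3
SER	CB,HB2,HB3,HG
THR	CB,CG2,HB,HG1,HG21,HG22,HG23
TRP	CB,CG,CD1,CD2,CE2,CE3,CZ2,CZ3,CH2,NE1,HB2,HB3,HD1,HE1,HE3,HZ2,HZ3,HH2
TYR	CB,CG,CD1,CD2,CE1,CE2,CZ,HB2,HB3,HD1,HD2,HE1,HE2,HH
VAL	CB,CG1,CG2,HB,HG11,HG12,HG13,HG21,HG22,HG23
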