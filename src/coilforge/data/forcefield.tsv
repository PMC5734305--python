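# coilforge soft-core force-field table, version 1
# columns: residue<TAB>atom<TAB>radius_A<TAB>hydrophobic(0/1)<TAB>formal_charge_e
# global term constants:
#set steric_repulsion 10.0
#set steric_well_depth 0.05
#set desolvation_strength 0.40
#set charge_strength 15.0
#set charge_min_distance 1.0
ALA	N	1.55	0	0.0
ALA	CA	1.70	0	0.0
ALA	C	1.70	0	0.0
ALA	O	1.52	0	0.0
ALA	CB	1.70	1	0.0
ARG	N	1.55	0	0.0
ARG	CA	1.70	0	0.0
ARG	C	1.70	0	0.0
ARG	O	1.52	0	0.0
ARG	CB	1.70	1	0.0
ARG	CG	1.70	1	0.0
ARG	CD	1.70	1	0.0
ARG	NE	1.55	0	0.0
ARG	CZ	1.70	1	1.0
ARG	NH1	1.55	0	0.0
ARG	NH2	1.55	0	0.0
ASN	N	1.55	0	0.0
ASN	CA	1.70	0	0.0
ASN	C	1.70	0	0.0
ASN	O	1.52	0	0.0
ASN	CB	1.70	1	0.0
ASN	CG	1.70	1	0.0
ASN	OD1	1.52	0	0.0
ASN	ND2	1.55	0	0.0
ASP	N	1.55	0	0.0
ASP	CA	1.70	0	0.0
ASP	C	1.70	0	0.0
ASP	O	1.52	0	0.0
ASP	CB	1.70	1	0.0
ASP	CG	1.70	1	-1.0
ASP	OD1	1.52	0	0.0
ASP	OD2	1.52	0	0.0
CYS	N	1.55	0	0.0
CYS	CA	1.70	0	0.0
CYS	C	1.70	0	0.0
CYS	O	1.52	0	0.0
CYS	CB	1.70	1	0.0
CYS	SG	1.80	1	0.0
GLN	N	1.55	0	0.0
GLN	CA	1.70	0	0.0
GLN	C	1.70	0	0.0
GLN	O	1.52	0	0.0
GLN	CB	1.70	1	0.0
GLN	CG	1.70	1	0.0
GLN	CD	1.70	1	0.0
GLN	OE1	1.52	0	0.0
GLN	NE2	1.55	0	0.0
GLU	N	1.55	0	0.0
GLU	CA	1.70	0	0.0
GLU	C	1.70	0	0.0
GLU	O	1.52	0	0.0
GLU	CB	1.70	1	0.0
GLU	CG	1.70	1	0.0
GLU	CD	1.70	1	-1.0
GLU	OE1	1.52	0	0.0
GLU	OE2	1.52	0	0.0
GLY	N	1.55	0	0.0
GLY	CA	1.70	0	0.0
GLY	C	1.70	0	0.0
GLY	O	1.52	0	0.0
HIS	N	1.55	0	0.0
HIS	CA	1.70	0	0.0
HIS	C	1.70	0	0.0
HIS	O	1.52	0	0.0
HIS	CB	1.70	1	0.0
HIS	CG	1.70	1	0.0
HIS	ND1	1.55	0	0.0
HIS	CD2	1.70	1	0.0
HIS	CE1	1.70	1	0.0
HIS	NE2	1.55	0	0.0
HYP	N	1.55	0	0.0
HYP	CA	1.70	0	0.0
HYP	C	1.70	0	0.0
HYP	O	1.52	0	0.0
HYP	CB	1.70	1	0.0
HYP	CG	1.70	1	0.0
HYP	CD	1.70	1	0.0
HYP	OD1	1.52	0	0.0
ILE	N	1.55	0	0.0
ILE	CA	1.70	0	0.0
ILE	C	1.70	0	0.0
ILE	O	1.52	0	0.0
ILE	CB	1.70	1	0.0
ILE	CG1	1.70	1	0.0
ILE	CG2	1.70	1	0.0
ILE	CD1	1.70	1	0.0
LEU	N	1.55	0	0.0
LEU	CA	1.70	0	0.0
LEU	C	1.70	0	0.0
LEU	O	1.52	0	0.0
LEU	CB	1.70	1	0.0
LEU	CG	1.70	1	0.0
LEU	CD1	1.70	1	0.0
LEU	CD2	1.70	1	0.0
LYS	N	1.55	0	0.0
LYS	CA	1.70	0	0.0
LYS	C	1.70	0	0.0
LYS	O	1.52	0	0.0
LYS	CB	1.70	1	0.0
LYS	CG	1.70	1	0.0
LYS	CD	1.70	1	0.0
LYS	CE	1.70	1	0.0
LYS	NZ	1.55	0	1.0
MET	N	1.55	0	0.0
MET	CA	1.70	0	0.0
MET	C	1.70	0	0.0
MET	O	1.52	0	0.0
MET	CB	1.70	1	0.0
MET	CG	1.70	1	0.0
MET	SD	1.80	1	0.0
MET	CE	1.70	1	0.0
PHE	N	1.55	0	0.0
PHE	CA	1.70	0	0.0
PHE	C	1.70	0	0.0
PHE	O	1.52	0	0.0
PHE	CB	1.70	1	0.0
PHE	CG	1.70	1	0.0
PHE	CD1	1.70	1	0.0
PHE	CD2	1.70	1	0.0
PHE	CE1	1.70	1	0.0
PHE	CE2	1.70	1	0.0
PHE	CZ	1.70	1	0.0
PRO	N	1.55	0	0.0
PRO	CA	1.70	0	0.0
PRO	C	1.70	0	0.0
PRO	O	1.52	0	0.0
PRO	CB	1.70	1	0.0
PRO	CG	1.70	1	0.0
PRO	CD	1.70	1	0.0
SER	N	1.55	0	0.0
SER	CA	1.70	0	0.0
SER	C	1.70	0	0.0
SER	O	1.52	0	0.0
SER	CB	1.70	1	0.0
SER	OG	1.52	0	0.0
THR	N	1.55	0	0.0
THR	CA	1.70	0	0.0
THR	C	1.70	0	0.0
THR	O	1.52	0	0.0
THR	CB	1.70	1	0.0
THR	OG1	1.52	0	0.0
THR	CG2	1.70	1	0.0
TRP	N	1.55	0	0.0
TRP	CA	1.70	0	0.0
TRP	C	1.70	0	0.0
TRP	O	1.52	0	0.0
TRP	CB	1.70	1	0.0
TRP	CG	1.70	1	0.0
TRP	CD1	1.70	1	0.0
TRP	CD2	1.70	1	0.0
TRP	NE1	1.55	0	0.0
TRP	CE2	1.70	1	0.0
TRP	CE3	1.70	1	0.0
TRP	CZ2	1.70	1	0.0
TRP	CZ3	1.70	1	0.0
TRP	CH2	1.70	1	0.0
TYR	N	1.55	0	0.0
TYR	CA	1.70	0	0.0
TYR	C	1.70	0	0.0
TYR	O	1.52	0	0.0
TYR	CB	1.70	1	0.0
TYR	CG	1.70	1	0.0
TYR	CD1	1.70	1	0.0
TYR	CD2	1.70	1	0.0
TYR	CE1	1.70	1	0.0
TYR	CE2	1.70	1	0.0
TYR	CZ	1.70	1	0.0
TYR	OH	1.52	0	0.0
VAL	N	1.55	0	0.0
VAL	CA	1.70	0	0.0
VAL	C	1.70	0	0.0
VAL	O	1.52	0	0.0
VAL	CB	1.70	1	0.0
VAL	CG1	1.70	1	0.0
VAL	CG2	1.70	1	0.0
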