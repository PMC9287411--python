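# Synthetic united-charge heavy-atom non-bonded parameter set (CHARMM-style conventions).
# Hydrogen partial charges are absorbed into their bonded heavy atom; per-residue charges
# sum exactly to the residue formal charge. Columns: residue, atom, q (e), epsilon
# (kcal/mol, well depth), rmin_half (Angstrom, half the distance at the pair minimum).
residue	atom	q	epsilon	rmin_half
ALA	N	-0.300	0.200	1.850
ALA	CA	0.100	0.078	2.040
ALA	C	0.550	0.078	2.040
ALA	O	-0.550	0.120	1.700
ALA	CB	0.200	0.078	2.040
ARG	N	-0.300	0.200	1.850
ARG	CA	0.100	0.078	2.040
ARG	C	0.550	0.078	2.040
ARG	O	-0.550	0.120	1.700
ARG	CB	0.000	0.078	2.040
ARG	CG	0.000	0.078	2.040
ARG	CD	0.200	0.078	2.040
ARG	NE	-0.200	0.200	1.850
ARG	CZ	0.600	0.078	2.040
ARG	NH1	0.300	0.200	1.850
ARG	NH2	0.300	0.200	1.850
ASN	N	-0.300	0.200	1.850
ASN	CA	0.100	0.078	2.040
ASN	C	0.550	0.078	2.040
ASN	O	-0.550	0.120	1.700
ASN	CB	0.100	0.078	2.040
ASN	CG	0.550	0.078	2.040
ASN	OD1	-0.550	0.120	1.700
ASN	ND2	0.100	0.200	1.850
ASP	N	-0.300	0.200	1.850
ASP	CA	0.100	0.078	2.040
ASP	C	0.550	0.078	2.040
ASP	O	-0.550	0.120	1.700
ASP	CB	0.000	0.078	2.040
ASP	CG	0.360	0.078	2.040
ASP	OD1	-0.580	0.120	1.700
ASP	OD2	-0.580	0.120	1.700
CYS	N	-0.300	0.200	1.850
CYS	CA	0.100	0.078	2.040
CYS	C	0.550	0.078	2.040
CYS	O	-0.550	0.120	1.700
CYS	CB	0.300	0.078	2.040
CYS	SG	-0.100	0.450	2.000
GLN	N	-0.300	0.200	1.850
GLN	CA	0.100	0.078	2.040
GLN	C	0.550	0.078	2.040
GLN	O	-0.550	0.120	1.700
GLN	CB	0.100	0.078	2.040
GLN	CG	0.000	0.078	2.040
GLN	CD	0.550	0.078	2.040
GLN	OE1	-0.550	0.120	1.700
GLN	NE2	0.100	0.200	1.850
GLU	N	-0.300	0.200	1.850
GLU	CA	0.100	0.078	2.040
GLU	C	0.550	0.078	2.040
GLU	O	-0.550	0.120	1.700
GLU	CB	0.000	0.078	2.040
GLU	CG	0.000	0.078	2.040
GLU	CD	0.360	0.078	2.040
GLU	OE1	-0.580	0.120	1.700
GLU	OE2	-0.580	0.120	1.700
GLY	N	-0.300	0.200	1.850
GLY	CA	0.300	0.078	2.040
GLY	C	0.550	0.078	2.040
GLY	O	-0.550	0.120	1.700
HIS	N	-0.300	0.200	1.850
HIS	CA	0.100	0.078	2.040
HIS	C	0.550	0.078	2.040
HIS	O	-0.550	0.120	1.700
HIS	CB	0.100	0.078	2.040
HIS	CG	0.000	0.078	2.040
HIS	ND1	-0.300	0.200	1.850
HIS	CD2	0.100	0.078	2.040
HIS	CE1	0.300	0.078	2.040
HIS	NE2	0.000	0.200	1.850
ILE	N	-0.300	0.200	1.850
ILE	CA	0.100	0.078	2.040
ILE	C	0.550	0.078	2.040
ILE	O	-0.550	0.120	1.700
ILE	CB	0.200	0.078	2.040
ILE	CG1	0.000	0.078	2.040
ILE	CG2	0.000	0.078	2.040
ILE	CD1	0.000	0.078	2.040
LEU	N	-0.300	0.200	1.850
LEU	CA	0.100	0.078	2.040
LEU	C	0.550	0.078	2.040
LEU	O	-0.550	0.120	1.700
LEU	CB	0.200	0.078	2.040
LEU	CG	0.000	0.078	2.040
LEU	CD1	0.000	0.078	2.040
LEU	CD2	0.000	0.078	2.040
LYS	N	-0.300	0.200	1.850
LYS	CA	0.100	0.078	2.040
LYS	C	0.550	0.078	2.040
LYS	O	-0.550	0.120	1.700
LYS	CB	0.000	0.078	2.040
LYS	CG	0.000	0.078	2.040
LYS	CD	0.000	0.078	2.040
LYS	CE	0.250	0.078	2.040
LYS	NZ	0.950	0.200	1.850
MET	N	-0.300	0.200	1.850
MET	CA	0.100	0.078	2.040
MET	C	0.550	0.078	2.040
MET	O	-0.550	0.120	1.700
MET	CB	0.200	0.078	2.040
MET	CG	0.060	0.078	2.040
MET	SD	-0.120	0.450	2.000
MET	CE	0.060	0.078	2.040
PHE	N	-0.300	0.200	1.850
PHE	CA	0.100	0.078	2.040
PHE	C	0.550	0.078	2.040
PHE	O	-0.550	0.120	1.700
PHE	CB	0.200	0.078	2.040
PHE	CG	0.000	0.078	2.040
PHE	CD1	0.000	0.078	2.040
PHE	CD2	0.000	0.078	2.040
PHE	CE1	0.000	0.078	2.040
PHE	CE2	0.000	0.078	2.040
PHE	CZ	0.000	0.078	2.040
PRO	N	-0.300	0.200	1.850
PRO	CA	0.100	0.078	2.040
PRO	C	0.550	0.078	2.040
PRO	O	-0.550	0.120	1.700
PRO	CB	0.100	0.078	2.040
PRO	CG	0.100	0.078	2.040
PRO	CD	0.000	0.078	2.040
SER	N	-0.300	0.200	1.850
SER	CA	0.100	0.078	2.040
SER	C	0.550	0.078	2.040
SER	O	-0.550	0.120	1.700
SER	CB	0.420	0.078	2.040
SER	OG	-0.220	0.120	1.700
THR	N	-0.300	0.200	1.850
THR	CA	0.100	0.078	2.040
THR	C	0.550	0.078	2.040
THR	O	-0.550	0.120	1.700
THR	CB	0.420	0.078	2.040
THR	OG1	-0.220	0.120	1.700
THR	CG2	0.000	0.078	2.040
TRP	N	-0.300	0.200	1.850
TRP	CA	0.100	0.078	2.040
TRP	C	0.550	0.078	2.040
TRP	O	-0.550	0.120	1.700
TRP	CB	0.200	0.078	2.040
TRP	CG	0.000	0.078	2.040
TRP	CD1	0.050	0.078	2.040
TRP	NE1	-0.550	0.200	1.850
TRP	CE2	0.300	0.078	2.040
TRP	CD2	0.000	0.078	2.040
TRP	CE3	0.000	0.078	2.040
TRP	CZ2	0.000	0.078	2.040
TRP	CZ3	0.000	0.078	2.040
TRP	CH2	0.200	0.078	2.040
TYR	N	-0.300	0.200	1.850
TYR	CA	0.100	0.078	2.040
TYR	C	0.550	0.078	2.040
TYR	O	-0.550	0.120	1.700
TYR	CB	0.200	0.078	2.040
TYR	CG	0.000	0.078	2.040
TYR	CD1	0.000	0.078	2.040
TYR	CD2	0.000	0.078	2.040
TYR	CE1	0.000	0.078	2.040
TYR	CE2	0.000	0.078	2.040
TYR	CZ	0.220	0.078	2.040
TYR	OH	-0.220	0.120	1.700
VAL	N	-0.300	0.200	1.850
VAL	CA	0.100	0.078	2.040
VAL	C	0.550	0.078	2.040
VAL	O	-0.550	0.120	1.700
VAL	CB	0.200	0.078	2.040
VAL	CG1	0.000	0.078	2.040
VAL	CG2	0.000	0.078	2.040
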