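# Synthetic water-affinity hydropathy scale (stand-in, see docstring of
# foldbind.composition_hydropathy). Orientation: H = 0.0 is the purely
# hydrophobic extreme and higher H means more hydrophilic. Values are an
# affine rescaling of the (inverted) Kyte-Doolittle index onto [0.0, 2.6]
# so that the hydrophobic/hydrophilic class thresholds 1.3 / 1.7 sit inside
# the range. It is NOT the molecular-dynamics-derived water-orientation
# scale; swap in that table to reproduce it exactly.
residue	H
ALA	0.78
ARG	2.60
ASN	2.31
ASP	2.31
CYS	0.58
GLN	2.31
GLU	2.31
GLY	1.42
HIS	2.22
ILE	0.00
LEU	0.20
LYS	2.43
MET	0.75
PHE	0.49
PRO	1.76
SER	1.53
THR	1.50
TRP	1.56
TYR	1.68
VAL	0.09
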