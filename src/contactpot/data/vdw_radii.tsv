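## Group Van der Waals radii for protein heavy atoms (hydrogens implicit).
## context: "aromatic" rows apply to ring atoms of PHE/TYR/TRP/HIS and take
## precedence over "*" rows; names ending in "**" are element-level wildcard
## fallbacks for atom names without an explicit row.
context	atom_name	radius_A
*	C	1.5
*	CA	2
*	CB	2
*	CD	2
aromatic	CD1	1.75
*	CD1	2
aromatic	CD2	1.75
*	CD2	2
*	CE	2
aromatic	CE1	1.75
aromatic	CE2	1.75
aromatic	CE3	1.75
aromatic	CG	1.75
*	CG	2
*	CG1	2
*	CG2	2
aromatic	CH2	1.75
*	CH3	2
aromatic	CZ	1.75
*	CZ	2
aromatic	CZ2	1.75
aromatic	CZ3	1.75
*	C**	2
*	N	1.55
*	ND1	1.55
*	ND2	1.55
*	NE	1.55
*	NE1	1.55
*	NE2	1.55
*	NH1	1.55
*	NH2	1.55
*	NZ	1.55
*	O	1.4
*	OD1	1.4
*	OD2	1.4
*	OE1	1.4
*	OE2	1.4
*	OG	1.4
*	OG1	1.4
*	OH	1.4
*	O**	1.44
*	S**	2
*	SD	2
*	SG	2
*	F**	2
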