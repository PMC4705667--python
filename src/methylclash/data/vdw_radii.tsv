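# Implicit-hydrogen van der Waals radii (Angstrom), first matching rule wins.
# kind: protein | dna | any; residues/atoms: comma lists or * wildcard.
kind	residues	atoms	radius	note
protein	ASP	OD1,OD2	1.5	carboxylate O
protein	GLU	OE1,OE2	1.5	carboxylate O
protein	ASP	CG	1.7	COOH carbon
protein	GLU	CD	1.7	COOH carbon
protein	ASN	OD1,ND2	1.6	amide O/N (CONH2 average)
protein	GLN	OE1,NE2	1.6	amide O/N (CONH2 average)
protein	ASN	CG	1.7	CONH2 carbon
protein	GLN	CD	1.7	CONH2 carbon
protein	HIS	CG,ND1,CD2,CE1,NE2	1.7	ring atom
protein	PHE	CG,CD1,CD2,CE1,CE2,CZ	1.7	ring atom
protein	TYR	CG,CD1,CD2,CE1,CE2,CZ	1.7	ring atom
protein	TYR	OH	1.6	hydroxyl
protein	TRP	CG,CD1,CD2,NE1,CE2,CE3,CZ2,CZ3,CH2	1.7	ring atom
protein	ARG	NE,CZ,NH1,NH2	1.7	guanidino group
protein	SER	OG	1.6	hydroxyl
protein	THR	OG1	1.6	hydroxyl
protein	LYS	NZ	2.0	Lys NH2
protein	MET	SD	1.8	S
protein	CYS	SG	1.8	S
protein	MSE	SE	1.8	Se treated as S
protein	*	N	1.7	main-chain NH
protein	*	C	1.7	main-chain carbonyl C
protein	*	O	1.4	main-chain O
protein	*	CA	2.0	C-alpha
protein	*	OXT	1.5	C-terminal carboxylate O
protein	*	CB,CG,CG1,CG2,CD,CD1,CD2,CE	2.0	aliphatic CH/CH2/CH3
protein	*	*	2.0	all other protein atoms
dna	DA,DG	N1,C2,N3,C4,C5,C6,N7,C8,N9	1.7	purine ring atom
dna	DC,DT	N1,C2,N3,C4,C5,C6	1.7	pyrimidine ring atom
dna	DA	N6	1.7	exocyclic NH2
dna	DG	N2	1.7	exocyclic NH2
dna	DC	N4	1.7	exocyclic NH2
dna	DG	O6	1.4	exocyclic O
dna	DC	O2	1.4	exocyclic O
dna	DT	O2,O4	1.4	exocyclic O
dna	DT	C7,C5M	2.0	thymine methyl
dna	*	OP1,OP2,OP3,O1P,O2P,O3P,O5',O4',O3',O2'	1.4	sugar/phosphate O
dna	*	P	1.8	phosphorus
dna	*	*	2.0	all other DNA atoms
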