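# residue	atom_name	sybyl	context
ALA	N	N.am	bk
ALA	CA	C.3	bk
ALA	C	C.2	bk
ALA	O	O.2	bk
ALA	OXT	O.co2	bk
ALA	CB	C.3	sc
ARG	N	N.am	bk
ARG	CA	C.3	bk
ARG	C	C.2	bk
ARG	O	O.2	bk
ARG	OXT	O.co2	bk
ARG	CB	C.3	sc
ARG	CG	C.3	sc
ARG	CD	C.3	sc
ARG	NE	N.pl3	sc
ARG	CZ	C.2	sc
ARG	NH1	N.pl3	sc
ARG	NH2	N.pl3	sc
ASN	N	N.am	bk
ASN	CA	C.3	bk
ASN	C	C.2	bk
ASN	O	O.2	bk
ASN	OXT	O.co2	bk
ASN	CB	C.3	sc
ASN	CG	C.2	sc
ASN	OD1	O.2	sc
ASN	ND2	N.am	sc
ASP	N	N.am	bk
ASP	CA	C.3	bk
ASP	C	C.2	bk
ASP	O	O.2	bk
ASP	OXT	O.co2	bk
ASP	CB	C.3	sc
ASP	CG	C.2	sc
ASP	OD1	O.co2	sc
ASP	OD2	O.co2	sc
CYS	N	N.am	bk
CYS	CA	C.3	bk
CYS	C	C.2	bk
CYS	O	O.2	bk
CYS	OXT	O.co2	bk
CYS	CB	C.3	sc
CYS	SG	S.3	sc
GLN	N	N.am	bk
GLN	CA	C.3	bk
GLN	C	C.2	bk
GLN	O	O.2	bk
GLN	OXT	O.co2	bk
GLN	CB	C.3	sc
GLN	CG	C.3	sc
GLN	CD	C.2	sc
GLN	OE1	O.2	sc
GLN	NE2	N.am	sc
GLU	N	N.am	bk
GLU	CA	C.3	bk
GLU	C	C.2	bk
GLU	O	O.2	bk
GLU	OXT	O.co2	bk
GLU	CB	C.3	sc
GLU	CG	C.3	sc
GLU	CD	C.2	sc
GLU	OE1	O.co2	sc
GLU	OE2	O.co2	sc
GLY	N	N.am	bk
GLY	CA	C.3	bk
GLY	C	C.2	bk
GLY	O	O.2	bk
GLY	OXT	O.co2	bk
HIS	N	N.am	bk
HIS	CA	C.3	bk
HIS	C	C.2	bk
HIS	O	O.2	bk
HIS	OXT	O.co2	bk
HIS	CB	C.3	sc
HIS	CG	C.ar	sc
HIS	ND1	N.ar	sc
HIS	CD2	C.ar	sc
HIS	CE1	C.ar	sc
HIS	NE2	N.ar	sc
ILE	N	N.am	bk
ILE	CA	C.3	bk
ILE	C	C.2	bk
ILE	O	O.2	bk
ILE	OXT	O.co2	bk
ILE	CB	C.3	sc
ILE	CG1	C.3	sc
ILE	CG2	C.3	sc
ILE	CD1	C.3	sc
LEU	N	N.am	bk
LEU	CA	C.3	bk
LEU	C	C.2	bk
LEU	O	O.2	bk
LEU	OXT	O.co2	bk
LEU	CB	C.3	sc
LEU	CG	C.3	sc
LEU	CD1	C.3	sc
LEU	CD2	C.3	sc
LYS	N	N.am	bk
LYS	CA	C.3	bk
LYS	C	C.2	bk
LYS	O	O.2	bk
LYS	OXT	O.co2	bk
LYS	CB	C.3	sc
LYS	CG	C.3	sc
LYS	CD	C.3	sc
LYS	CE	C.3	sc
LYS	NZ	N.4	sc
MET	N	N.am	bk
MET	CA	C.3	bk
MET	C	C.2	bk
MET	O	O.2	bk
MET	OXT	O.co2	bk
MET	CB	C.3	sc
MET	CG	C.3	sc
MET	SD	S.3	sc
MET	CE	C.3	sc
PHE	N	N.am	bk
PHE	CA	C.3	bk
PHE	C	C.2	bk
PHE	O	O.2	bk
PHE	OXT	O.co2	bk
PHE	CB	C.3	sc
PHE	CG	C.ar	sc
PHE	CD1	C.ar	sc
PHE	CD2	C.ar	sc
PHE	CE1	C.ar	sc
PHE	CE2	C.ar	sc
PHE	CZ	C.ar	sc
PRO	N	N.am	bk
PRO	CA	C.3	bk
PRO	C	C.2	bk
PRO	O	O.2	bk
PRO	OXT	O.co2	bk
PRO	CB	C.3	sc
PRO	CG	C.3	sc
PRO	CD	C.3	sc
SER	N	N.am	bk
SER	CA	C.3	bk
SER	C	C.2	bk
SER	O	O.2	bk
SER	OXT	O.co2	bk
SER	CB	C.3	sc
SER	OG	O.3	sc
THR	N	N.am	bk
THR	CA	C.3	bk
THR	C	C.2	bk
THR	O	O.2	bk
THR	OXT	O.co2	bk
THR	CB	C.3	sc
THR	OG1	O.3	sc
THR	CG2	C.3	sc
TRP	N	N.am	bk
TRP	CA	C.3	bk
TRP	C	C.2	bk
TRP	O	O.2	bk
TRP	OXT	O.co2	bk
TRP	CB	C.3	sc
TRP	CG	C.ar	sc
TRP	CD1	C.ar	sc
TRP	CD2	C.ar	sc
TRP	NE1	N.ar	sc
TRP	CE2	C.ar	sc
TRP	CE3	C.ar	sc
TRP	CZ2	C.ar	sc
TRP	CZ3	C.ar	sc
TRP	CH2	C.ar	sc
TYR	N	N.am	bk
TYR	CA	C.3	bk
TYR	C	C.2	bk
TYR	O	O.2	bk
TYR	OXT	O.co2	bk
TYR	CB	C.3	sc
TYR	CG	C.ar	sc
TYR	CD1	C.ar	sc
TYR	CD2	C.ar	sc
TYR	CE1	C.ar	sc
TYR	CE2	C.ar	sc
TYR	CZ	C.ar	sc
TYR	OH	O.3	sc
VAL	N	N.am	bk
VAL	CA	C.3	bk
VAL	C	C.2	bk
VAL	O	O.2	bk
VAL	OXT	O.co2	bk
VAL	CB	C.3	sc
VAL	CG1	C.3	sc
VAL	CG2	C.3	sc
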