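# Extra covalent bonds not reachable by covalent-radii perception.
# Columns: resname1 atom1 resname2 atom2 max_dist(Å)
# c-type heme: thioether links to Cys, Fe-porphyrin and axial ligations
HEC	CAB	CYS	SG	2.5
HEC	CAC	CYS	SG	2.5
HEC	FE	HEC	NA	2.6
HEC	FE	HEC	NB	2.6
HEC	FE	HEC	NC	2.6
HEC	FE	HEC	ND	2.6
HEC	FE	HIS	NE2	3.0
HEC	FE	MET	SD	3.2
# binuclear Cu_A site ligations (copper residue deposited as CU or CU1)
CU	CU	CYS	SG	3.0
CU	CU	HIS	ND1	2.8
CU	CU	MET	SD	3.4
CU	CU	GLU	O	3.0
CU1	CU1	CYS	SG	3.0
CU1	CU1	HIS	ND1	2.8
CU1	CU1	MET	SD	3.4
CU1	CU1	GLU	O	3.0
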