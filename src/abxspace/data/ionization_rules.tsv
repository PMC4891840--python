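name	smarts	atom_index	action	pka
carboxylic_acid	[CX3](=O)[OX2H1]	2	deprotonate	4.2
sulfonic_acid	[SX4](=O)(=O)[OX2H1]	3	deprotonate	-1.0
phosphonic_acid	[PX4](=O)[OX2H1]	2	deprotonate	2.0
tetrazole	[nX3H1]1nnnc1	0	deprotonate	4.9
acyl_sulfonamide	[SX4](=O)(=O)[NX3H1][CX3]=[OX1]	3	deprotonate	4.5
guanidine	[NX3][CX3](=[NX2;!$(N-a)])[NX3]	2	protonate	13.6
amidine	[NX3][CX3]=[NX2;!$(N-a)]	2	protonate	12.4
primary_amine	[NX3;H2;+0;!$(NC=[O,S,N]);!$(N[a]);!$(NS(=O)=O);!$(NO);!$(NN)]	0	protonate	10.6
secondary_amine	[NX3;H1;+0;!$(NC=[O,S,N]);!$(N[a]);!$(NS(=O)=O);!$(NO);!$(NN);!$(N=*)]	0	protonate	10.8
tertiary_amine	[NX3;H0;+0;!$(NC=[O,S,N]);!$(N[a]);!$(NS(=O)=O);!$(N~[OX1]);!$(N=*);!$(N#*)]	0	protonate	9.8
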