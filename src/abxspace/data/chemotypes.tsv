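name	smarts	site_of_action	min_count
beta_lactam	O=C1[#6][#6]N1	cell_wall	40
fluoroquinolone	O=C(O)c1cn(*)c2ccccc2c1=O	cytoplasmic	40
oxazolidinone	O=C1OCCN1	cytoplasmic	40
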