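organism	gram_class
Staphylococcus aureus	gram_positive
Staphylococcus epidermidis	gram_positive
Staphylococcus	gram_positive
Enterococcus faecalis	gram_positive
Enterococcus faecium	gram_positive
Enterococcus	gram_positive
Streptococcus pneumoniae	gram_positive
Streptococcus pyogenes	gram_positive
Streptococcus	gram_positive
Bacillus subtilis	gram_positive
Bacillus	gram_positive
Listeria monocytogenes	gram_positive
Listeria	gram_positive
Clostridium difficile	gram_positive
Clostridium	gram_positive
Escherichia coli	gram_negative
Escherichia	gram_negative
Klebsiella pneumoniae	gram_negative
Klebsiella	gram_negative
Pseudomonas aeruginosa	gram_negative
Pseudomonas	gram_negative
Enterobacter cloacae	gram_negative
Enterobacter	gram_negative
Acinetobacter baumannii	gram_negative
Acinetobacter	gram_negative
Haemophilus influenzae	gram_negative
Haemophilus	gram_negative
Salmonella enterica	gram_negative
Salmonella	gram_negative
Neisseria gonorrhoeae	gram_negative
Neisseria	gram_negative
Proteus mirabilis	gram_negative
Proteus	gram_negative
Serratia marcescens	gram_negative
Serratia	gram_negative
Moraxella catarrhalis	gram_negative
Campylobacter jejuni	gram_negative
Helicobacter pylori	gram_negative
Vibrio cholerae	gram_negative
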