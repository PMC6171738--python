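source,target,percent,provenance
TK,GABA,84.6,reported GABA coexpression percentage
FMRF,GABA,92.8,reported GABA coexpression percentage
Mas-AT,GABA,97.2,reported GABA coexpression percentage
MIP,GABA,97.5,reported GABA coexpression percentage
AST-A,GABA,96.7,reported GABA coexpression percentage
TK,MIP,100,reported peptide-peptide coexpression (all-or-none TK pattern)
TK,FMRF,0,reported peptide-peptide coexpression (all-or-none TK pattern)
TK,Mas-AT,0,reported peptide-peptide coexpression (all-or-none TK pattern)
MIP,Mas-AT,42,reported peptide-peptide coexpression
Mas-AT,FMRF,22,reported peptide-peptide coexpression
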