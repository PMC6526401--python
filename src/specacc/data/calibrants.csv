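name,neutral_formula,adduct
caffeine,C8H10N4O2,[M+H]+
atrazine,C8H14ClN5,[M+H]+
cyclophosphamide,C7H15Cl2N2O2P,[M+H]+
metoprolol,C15H25NO3,[M+H]+
avobenzone,C20H22O3,[M+H]+
benzylbutyl_phthalate,C19H20O4,[M+Na]+
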