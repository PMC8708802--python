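# Ion-pairing reagent definitions. Formulas are neutral compositions;
# charges are integers. reagent_fragment is the +1 ion the reagent itself
# yields under HCD (the dication after neutral loss and loss of H+).
# name	dication_formula	dication_charge	neutral_loss_formula	reagent_fragment_formula	counterion_formula
C5(bpyr)2	C21H44N2	2	C8H17N	C13H26N	F
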