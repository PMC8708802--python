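# Lipid-class fragmentation rules for dication adducts under HCD.
# headgroup_neutral_formula: the neutral (protonated) polar headgroup; the
# diagnostic fragment is its anion paired with the reagent dication after
# the reagent's neutral loss. secondary_neutral_loss: an additional neutral
# loss from the headgroup fragment (ethanimine C2H5N for PE). "-" = none:
# the class is known but has no headgroup-anion rule (fatty acids have no
# headgroup; PC appears protonated, not adducted).
# lipid_class	headgroup_neutral_formula	secondary_neutral_loss
PA	H3PO4	-
PE	C2H8NO4P	C2H5N
PI	C6H13O9P	-
FA	-	-
PC	-	-
DG	-	-
TG	-	-
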