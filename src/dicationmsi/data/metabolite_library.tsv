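# Offline metabolite formula library (glycerophospholipids,
# fatty acids, glycerides) with LIPID MAPS-style shorthand names.
# expected_polarity: negative = deprotonates readily (FA/PA/PI),
# positive = protonates readily (PC/DG/TG), both = PE.
# name	formula	lipid_class	expected_polarity
FA(14:0)	C14H28O2	FA	negative
FA(16:0)	C16H32O2	FA	negative
FA(16:1)	C16H30O2	FA	negative
FA(18:0)	C18H36O2	FA	negative
FA(18:1)	C18H34O2	FA	negative
FA(18:2)	C18H32O2	FA	negative
FA(18:3)	C18H30O2	FA	negative
FA(20:0)	C20H40O2	FA	negative
FA(20:1)	C20H38O2	FA	negative
FA(20:2)	C20H36O2	FA	negative
FA(20:3)	C20H34O2	FA	negative
FA(20:4)	C20H32O2	FA	negative
FA(20:5)	C20H30O2	FA	negative
FA(22:4)	C22H36O2	FA	negative
FA(22:5)	C22H34O2	FA	negative
FA(22:6)	C22H32O2	FA	negative
FA(24:0)	C24H48O2	FA	negative
FA(24:1)	C24H46O2	FA	negative
PA(32:0)	C35H69O8P	PA	negative
PA(34:1)	C37H71O8P	PA	negative
PA(36:2)	C39H73O8P	PA	negative
PA(38:4)	C41H73O8P	PA	negative
PA(38:5)	C41H71O8P	PA	negative
PA(40:6)	C43H73O8P	PA	negative
PE(34:1)	C39H76NO8P	PE	both
PE(34:2)	C39H74NO8P	PE	both
PE(36:1)	C41H80NO8P	PE	both
PE(36:2)	C41H78NO8P	PE	both
PE(36:4)	C41H74NO8P	PE	both
PE(38:4)	C43H78NO8P	PE	both
PE(38:6)	C43H74NO8P	PE	both
PE(40:6)	C45H78NO8P	PE	both
PI(34:1)	C43H81O13P	PI	negative
PI(36:2)	C45H83O13P	PI	negative
PI(38:4)	C47H83O13P	PI	negative
PI(38:5)	C47H81O13P	PI	negative
PI(40:6)	C49H83O13P	PI	negative
PC(30:0)	C38H76NO8P	PC	positive
PC(32:0)	C40H80NO8P	PC	positive
PC(32:1)	C40H78NO8P	PC	positive
PC(34:1)	C42H82NO8P	PC	positive
PC(34:2)	C42H80NO8P	PC	positive
PC(36:1)	C44H86NO8P	PC	positive
PC(36:2)	C44H84NO8P	PC	positive
PC(36:4)	C44H80NO8P	PC	positive
PC(38:4)	C46H84NO8P	PC	positive
PC(38:6)	C46H80NO8P	PC	positive
DG(32:0)	C35H68O5	DG	positive
DG(34:1)	C37H70O5	DG	positive
DG(36:2)	C39H72O5	DG	positive
DG(36:4)	C39H68O5	DG	positive
DG(38:4)	C41H72O5	DG	positive
DG(38:6)	C41H68O5	DG	positive
TG(48:0)	C51H98O6	TG	positive
TG(50:1)	C53H100O6	TG	positive
TG(52:2)	C55H102O6	TG	positive
TG(52:3)	C55H100O6	TG	positive
TG(54:2)	C57H106O6	TG	positive
TG(54:4)	C57H102O6	TG	positive
TG(54:6)	C57H98O6	TG	positive
TG(56:8)	C59H98O6	TG	positive
PC(36:3)	C44H82NO8P	PC	positive
PC(38:2)	C46H88NO8P	PC	positive
PC(38:5)	C46H82NO8P	PC	positive
PC(40:6)	C48H84NO8P	PC	positive
DG(34:0)	C37H72O5	DG	positive
TG(50:2)	C53H98O6	TG	positive
TG(52:4)	C55H98O6	TG	positive
TG(56:6)	C59H102O6	TG	positive
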