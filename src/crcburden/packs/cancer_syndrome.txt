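# Genes predisposing to other cancer types or causing recessive cancer
# syndromes when biallelically mutated. Editable starter list.
ATM
BLM
BRIP1
WRN
ERCC3
EGFR
BRCA1
BRCA2
CHEK2
PALB2
NBN
FANCA
FANCC
XPC
RECQL4
TP53
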