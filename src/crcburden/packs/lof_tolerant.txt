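# Genes that tolerate loss-of-function variation in healthy populations;
# variants here are excluded from candidacy. Editable starter list.
OR2T33
OR4C46
OR51A2
UGT2B17
KRTAP4-11
FLG
MUC16
PRAMEF2
TAS2R43
CDC27
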