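# Genes with established germline colorectal-cancer predisposition
# (Lynch-syndrome mismatch-repair genes, polyposis genes, polymerase
# proofreading genes). Editable; symbols are case-normalised at load.
MLH1
MSH2
MSH6
PMS2
EPCAM
APC
MUTYH
NTHL1
POLE
POLD1
SMAD4
BMPR1A
STK11
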