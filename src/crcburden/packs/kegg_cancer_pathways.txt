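# Union of genes in cancer-related KEGG pathways: WNT signalling
# (hsa04310), TGF-beta signalling (hsa04350), mismatch repair (hsa03430),
# base excision repair (hsa03410), nucleotide excision repair (hsa03420),
# non-homologous end-joining (map03450), Fanconi anaemia (hsa03460) and
# pathways in cancer (hsa05200). Version: starter snapshot; pathway
# databases drift, pin an export for production use.
LRP5
LRP6
APC
CTNNB1
AXIN1
AXIN2
TCF7L2
WNT3A
DVL1
GSK3B
SMAD2
SMAD3
SMAD4
TGFBR1
TGFBR2
BMP4
MLH1
MSH2
MSH6
PMS2
OGG1
MUTYH
NTHL1
APEX1
ERCC1
ERCC3
XPA
XPC
LIG4
XRCC4
PRKDC
FANCA
FANCC
FANCD2
BRCA2
TP53
KRAS
PIK3CA
EGFR
PTEN
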