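# Genes at loci associated with colorectal cancer in genome-wide
# association studies. Editable starter list.
GREM1
SMAD7
CDH1
RHPN2
BMP2
BMP4
CCAT2
POU5F1B
EIF3H
TERT
CRAC1
COLCA1
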