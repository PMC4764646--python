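# Candidate CRC susceptibility genes from transposon-based insertional
# mutagenesis screens in mice. Editable starter list.
LRP6
PTEN
RSPO2
BMP4
TCF12
STAG1
MYO5B
PARD3
RASGRF1
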