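# Genes recurrently somatically mutated in colorectal tumours (driver
# catalogue). Version: starter snapshot shipped with the package; replace
# with a pinned catalogue export for production use.
APC
TP53
KRAS
NRAS
BRAF
PIK3CA
SMAD4
FBXW7
TCF7L2
SOX9
ARID1A
MSH6
TTN
PTPN12
ACVR2A
AMER1
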