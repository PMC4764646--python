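list_id	filename
crc_predisposition	crc_predisposition.txt
cancer_syndrome	cancer_syndrome.txt
lof_tolerant	lof_tolerant.txt
crc_driver	crc_driver.txt
mouse_transposon	mouse_transposon.txt
kegg_cancer_pathways	kegg_cancer_pathways.txt
gwas	gwas.txt
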