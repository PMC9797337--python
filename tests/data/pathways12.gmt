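GO:0001	inflammatory_response	NOTCH1	NOTCH2	IL6	TNF
GO:0002	nfkb_signaling_positive_regulation	NFKB1	RELA	TNF	IL6
GO:0003	treg_differentiation	NOTCH4	FOXP3	IL2RA
GO:0004	spliceosome_assembly	SF3B1	U2AF1
GO:0005	hemophagocytic_lymphohistiocytosis	AP3B1	PRF1	LYST	DOCK8
GO:0006	notch_negative_regulation	NUMB	NUMBL	NOTCH1
GO:0007	cytokine_production	IL6	IL10	IFNG
GO:0008	rbpj_like	RBPJL
KEGG:hsa04330	notch_signaling	NOTCH1	NOTCH2	NOTCH4	RBPJL	NUMB	NUMBL
KEGG:hsa04630	jak_stat_signaling	IFNG	IL10	STAT1	STAT3
KEGG:hsa04064	nfkb_signaling	NFKB1	RELA	TNF
CUSTOM:01	immune_panel	DOCK8	STAT1	FOXP3	GATA3
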