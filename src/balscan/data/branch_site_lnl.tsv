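# Branch-site codon-model log-likelihoods for the three psychiatric-disorder
# candidate genes (human foreground lineage), as published; inputs to the
# LRT arithmetic. Columns: gene, lnL of the null model, lnL of the
# alternative model.
gene	lnl_null	lnl_alt
CLSTN2	-9148.16	-9143.78
FAT1	-62480.72	-62474.75
SLC18A1	-7085.21	-7083.08
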