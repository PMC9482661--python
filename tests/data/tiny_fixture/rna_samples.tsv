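sample	stage	genotype	replicate
RNA_WT_D0_r1	D0	WT	1
RNA_WT_D0_r2	D0	WT	2
RNA_WT_D0_r3	D0	WT	3
RNA_WT_D0_r4	D0	WT	4
RNA_WT_D15_r1	D15	WT	1
RNA_WT_D15_r2	D15	WT	2
RNA_WT_D15_r3	D15	WT	3
RNA_WT_D15_r4	D15	WT	4
RNA_WT_D35_r1	D35	WT	1
RNA_WT_D35_r2	D35	WT	2
RNA_WT_D35_r3	D35	WT	3
RNA_WT_D35_r4	D35	WT	4
RNA_HET_D0_r1	D0	HET	1
RNA_HET_D0_r2	D0	HET	2
RNA_HET_D0_r3	D0	HET	3
RNA_HET_D0_r4	D0	HET	4
RNA_HET_D15_r1	D15	HET	1
RNA_HET_D15_r2	D15	HET	2
RNA_HET_D15_r3	D15	HET	3
RNA_HET_D15_r4	D15	HET	4
RNA_HET_D35_r1	D35	HET	1
RNA_HET_D35_r2	D35	HET	2
RNA_HET_D35_r3	D35	HET	3
RNA_HET_D35_r4	D35	HET	4
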