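sample	mark	stage	genotype	replicate	path
CHD2_D0_HET_rep1	CHD2	D0	HET	1	peaks/CHD2_D0_HET_rep1.bed
CHD2_D0_HET_rep2	CHD2	D0	HET	2	peaks/CHD2_D0_HET_rep2.bed
CHD2_D0_HET_rep3	CHD2	D0	HET	3	peaks/CHD2_D0_HET_rep3.bed
CHD2_D0_HET_rep4	CHD2	D0	HET	4	peaks/CHD2_D0_HET_rep4.bed
CHD2_D0_WT_rep1	CHD2	D0	WT	1	peaks/CHD2_D0_WT_rep1.bed
CHD2_D0_WT_rep2	CHD2	D0	WT	2	peaks/CHD2_D0_WT_rep2.bed
CHD2_D0_WT_rep3	CHD2	D0	WT	3	peaks/CHD2_D0_WT_rep3.bed
CHD2_D0_WT_rep4	CHD2	D0	WT	4	peaks/CHD2_D0_WT_rep4.bed
CHD2_D15_HET_rep1	CHD2	D15	HET	1	peaks/CHD2_D15_HET_rep1.bed
CHD2_D15_HET_rep2	CHD2	D15	HET	2	peaks/CHD2_D15_HET_rep2.bed
CHD2_D15_HET_rep3	CHD2	D15	HET	3	peaks/CHD2_D15_HET_rep3.bed
CHD2_D15_HET_rep4	CHD2	D15	HET	4	peaks/CHD2_D15_HET_rep4.bed
CHD2_D15_WT_rep1	CHD2	D15	WT	1	peaks/CHD2_D15_WT_rep1.bed
CHD2_D15_WT_rep2	CHD2	D15	WT	2	peaks/CHD2_D15_WT_rep2.bed
CHD2_D15_WT_rep3	CHD2	D15	WT	3	peaks/CHD2_D15_WT_rep3.bed
CHD2_D15_WT_rep4	CHD2	D15	WT	4	peaks/CHD2_D15_WT_rep4.bed
CHD2_D35_HET_rep1	CHD2	D35	HET	1	peaks/CHD2_D35_HET_rep1.bed
CHD2_D35_HET_rep2	CHD2	D35	HET	2	peaks/CHD2_D35_HET_rep2.bed
CHD2_D35_HET_rep3	CHD2	D35	HET	3	peaks/CHD2_D35_HET_rep3.bed
CHD2_D35_HET_rep4	CHD2	D35	HET	4	peaks/CHD2_D35_HET_rep4.bed
CHD2_D35_WT_rep1	CHD2	D35	WT	1	peaks/CHD2_D35_WT_rep1.bed
CHD2_D35_WT_rep2	CHD2	D35	WT	2	peaks/CHD2_D35_WT_rep2.bed
CHD2_D35_WT_rep3	CHD2	D35	WT	3	peaks/CHD2_D35_WT_rep3.bed
CHD2_D35_WT_rep4	CHD2	D35	WT	4	peaks/CHD2_D35_WT_rep4.bed
H3K27ac_D0_HET_rep1	H3K27ac	D0	HET	1	peaks/H3K27ac_D0_HET_rep1.bed
H3K27ac_D0_HET_rep2	H3K27ac	D0	HET	2	peaks/H3K27ac_D0_HET_rep2.bed
H3K27ac_D0_HET_rep3	H3K27ac	D0	HET	3	peaks/H3K27ac_D0_HET_rep3.bed
H3K27ac_D0_HET_rep4	H3K27ac	D0	HET	4	peaks/H3K27ac_D0_HET_rep4.bed
H3K27ac_D0_WT_rep1	H3K27ac	D0	WT	1	peaks/H3K27ac_D0_WT_rep1.bed
H3K27ac_D0_WT_rep2	H3K27ac	D0	WT	2	peaks/H3K27ac_D0_WT_rep2.bed
H3K27ac_D0_WT_rep3	H3K27ac	D0	WT	3	peaks/H3K27ac_D0_WT_rep3.bed
H3K27ac_D0_WT_rep4	H3K27ac	D0	WT	4	peaks/H3K27ac_D0_WT_rep4.bed
H3K27ac_D15_HET_rep1	H3K27ac	D15	HET	1	peaks/H3K27ac_D15_HET_rep1.bed
H3K27ac_D15_HET_rep2	H3K27ac	D15	HET	2	peaks/H3K27ac_D15_HET_rep2.bed
H3K27ac_D15_HET_rep3	H3K27ac	D15	HET	3	peaks/H3K27ac_D15_HET_rep3.bed
H3K27ac_D15_HET_rep4	H3K27ac	D15	HET	4	peaks/H3K27ac_D15_HET_rep4.bed
H3K27ac_D15_WT_rep1	H3K27ac	D15	WT	1	peaks/H3K27ac_D15_WT_rep1.bed
H3K27ac_D15_WT_rep2	H3K27ac	D15	WT	2	peaks/H3K27ac_D15_WT_rep2.bed
H3K27ac_D15_WT_rep3	H3K27ac	D15	WT	3	peaks/H3K27ac_D15_WT_rep3.bed
H3K27ac_D15_WT_rep4	H3K27ac	D15	WT	4	peaks/H3K27ac_D15_WT_rep4.bed
H3K27ac_D35_HET_rep1	H3K27ac	D35	HET	1	peaks/H3K27ac_D35_HET_rep1.bed
H3K27ac_D35_HET_rep2	H3K27ac	D35	HET	2	peaks/H3K27ac_D35_HET_rep2.bed
H3K27ac_D35_HET_rep3	H3K27ac	D35	HET	3	peaks/H3K27ac_D35_HET_rep3.bed
H3K27ac_D35_HET_rep4	H3K27ac	D35	HET	4	peaks/H3K27ac_D35_HET_rep4.bed
H3K27ac_D35_WT_rep1	H3K27ac	D35	WT	1	peaks/H3K27ac_D35_WT_rep1.bed
H3K27ac_D35_WT_rep2	H3K27ac	D35	WT	2	peaks/H3K27ac_D35_WT_rep2.bed
H3K27ac_D35_WT_rep3	H3K27ac	D35	WT	3	peaks/H3K27ac_D35_WT_rep3.bed
H3K27ac_D35_WT_rep4	H3K27ac	D35	WT	4	peaks/H3K27ac_D35_WT_rep4.bed
H3K27me3_D0_HET_rep1	H3K27me3	D0	HET	1	peaks/H3K27me3_D0_HET_rep1.bed
H3K27me3_D0_HET_rep2	H3K27me3	D0	HET	2	peaks/H3K27me3_D0_HET_rep2.bed
H3K27me3_D0_HET_rep3	H3K27me3	D0	HET	3	peaks/H3K27me3_D0_HET_rep3.bed
H3K27me3_D0_HET_rep4	H3K27me3	D0	HET	4	peaks/H3K27me3_D0_HET_rep4.bed
H3K27me3_D0_WT_rep1	H3K27me3	D0	WT	1	peaks/H3K27me3_D0_WT_rep1.bed
H3K27me3_D0_WT_rep2	H3K27me3	D0	WT	2	peaks/H3K27me3_D0_WT_rep2.bed
H3K27me3_D0_WT_rep3	H3K27me3	D0	WT	3	peaks/H3K27me3_D0_WT_rep3.bed
H3K27me3_D0_WT_rep4	H3K27me3	D0	WT	4	peaks/H3K27me3_D0_WT_rep4.bed
H3K27me3_D15_HET_rep1	H3K27me3	D15	HET	1	peaks/H3K27me3_D15_HET_rep1.bed
H3K27me3_D15_HET_rep2	H3K27me3	D15	HET	2	peaks/H3K27me3_D15_HET_rep2.bed
H3K27me3_D15_HET_rep3	H3K27me3	D15	HET	3	peaks/H3K27me3_D15_HET_rep3.bed
H3K27me3_D15_HET_rep4	H3K27me3	D15	HET	4	peaks/H3K27me3_D15_HET_rep4.bed
H3K27me3_D15_WT_rep1	H3K27me3	D15	WT	1	peaks/H3K27me3_D15_WT_rep1.bed
H3K27me3_D15_WT_rep2	H3K27me3	D15	WT	2	peaks/H3K27me3_D15_WT_rep2.bed
H3K27me3_D15_WT_rep3	H3K27me3	D15	WT	3	peaks/H3K27me3_D15_WT_rep3.bed
H3K27me3_D15_WT_rep4	H3K27me3	D15	WT	4	peaks/H3K27me3_D15_WT_rep4.bed
H3K27me3_D35_HET_rep1	H3K27me3	D35	HET	1	peaks/H3K27me3_D35_HET_rep1.bed
H3K27me3_D35_HET_rep2	H3K27me3	D35	HET	2	peaks/H3K27me3_D35_HET_rep2.bed
H3K27me3_D35_HET_rep3	H3K27me3	D35	HET	3	peaks/H3K27me3_D35_HET_rep3.bed
H3K27me3_D35_HET_rep4	H3K27me3	D35	HET	4	peaks/H3K27me3_D35_HET_rep4.bed
H3K27me3_D35_WT_rep1	H3K27me3	D35	WT	1	peaks/H3K27me3_D35_WT_rep1.bed
H3K27me3_D35_WT_rep2	H3K27me3	D35	WT	2	peaks/H3K27me3_D35_WT_rep2.bed
H3K27me3_D35_WT_rep3	H3K27me3	D35	WT	3	peaks/H3K27me3_D35_WT_rep3.bed
H3K27me3_D35_WT_rep4	H3K27me3	D35	WT	4	peaks/H3K27me3_D35_WT_rep4.bed
H3K4me3_D0_HET_rep1	H3K4me3	D0	HET	1	peaks/H3K4me3_D0_HET_rep1.bed
H3K4me3_D0_HET_rep2	H3K4me3	D0	HET	2	peaks/H3K4me3_D0_HET_rep2.bed
H3K4me3_D0_HET_rep3	H3K4me3	D0	HET	3	peaks/H3K4me3_D0_HET_rep3.bed
H3K4me3_D0_HET_rep4	H3K4me3	D0	HET	4	peaks/H3K4me3_D0_HET_rep4.bed
H3K4me3_D0_WT_rep1	H3K4me3	D0	WT	1	peaks/H3K4me3_D0_WT_rep1.bed
H3K4me3_D0_WT_rep2	H3K4me3	D0	WT	2	peaks/H3K4me3_D0_WT_rep2.bed
H3K4me3_D0_WT_rep3	H3K4me3	D0	WT	3	peaks/H3K4me3_D0_WT_rep3.bed
H3K4me3_D0_WT_rep4	H3K4me3	D0	WT	4	peaks/H3K4me3_D0_WT_rep4.bed
H3K4me3_D15_HET_rep1	H3K4me3	D15	HET	1	peaks/H3K4me3_D15_HET_rep1.bed
H3K4me3_D15_HET_rep2	H3K4me3	D15	HET	2	peaks/H3K4me3_D15_HET_rep2.bed
H3K4me3_D15_HET_rep3	H3K4me3	D15	HET	3	peaks/H3K4me3_D15_HET_rep3.bed
H3K4me3_D15_HET_rep4	H3K4me3	D15	HET	4	peaks/H3K4me3_D15_HET_rep4.bed
H3K4me3_D15_WT_rep1	H3K4me3	D15	WT	1	peaks/H3K4me3_D15_WT_rep1.bed
H3K4me3_D15_WT_rep2	H3K4me3	D15	WT	2	peaks/H3K4me3_D15_WT_rep2.bed
H3K4me3_D15_WT_rep3	H3K4me3	D15	WT	3	peaks/H3K4me3_D15_WT_rep3.bed
H3K4me3_D15_WT_rep4	H3K4me3	D15	WT	4	peaks/H3K4me3_D15_WT_rep4.bed
H3K4me3_D35_HET_rep1	H3K4me3	D35	HET	1	peaks/H3K4me3_D35_HET_rep1.bed
H3K4me3_D35_HET_rep2	H3K4me3	D35	HET	2	peaks/H3K4me3_D35_HET_rep2.bed
H3K4me3_D35_HET_rep3	H3K4me3	D35	HET	3	peaks/H3K4me3_D35_HET_rep3.bed
H3K4me3_D35_HET_rep4	H3K4me3	D35	HET	4	peaks/H3K4me3_D35_HET_rep4.bed
H3K4me3_D35_WT_rep1	H3K4me3	D35	WT	1	peaks/H3K4me3_D35_WT_rep1.bed
H3K4me3_D35_WT_rep2	H3K4me3	D35	WT	2	peaks/H3K4me3_D35_WT_rep2.bed
H3K4me3_D35_WT_rep3	H3K4me3	D35	WT	3	peaks/H3K4me3_D35_WT_rep3.bed
H3K4me3_D35_WT_rep4	H3K4me3	D35	WT	4	peaks/H3K4me3_D35_WT_rep4.bed
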