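chr1	11578	12551	peak0022_r3	0	.
chr1	20698	21698	peak0007_r3	0	.
chr1	72577	73576	peak0008_r3	0	.
chr1	120282	121317	peak0042_r3	0	.
chr1	150610	151610	noise_H3K27me3_D35_WT_r3_0	0	.
chr1	181498	182501	peak0050_r3	0	.
chr1	193970	194970	noise_H3K27me3_D35_WT_r3_2	0	.
chr2	3304	4301	peak0051_r3	0	.
chr2	11324	12324	noise_H3K27me3_D35_WT_r3_3	0	.
chr2	23710	24710	noise_H3K27me3_D35_WT_r3_1	0	.
chr2	47766	48748	peak0000_r3	0	.
chr2	67527	68526	peak0004_r3	0	.
chr2	117487	118491	peak0049_r3	0	.
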