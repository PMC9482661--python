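chr1	3565	4161	peak0032_r1	0	.
chr1	20894	21507	peak0007_r1	0	.
chr1	26711	27308	peak0046_r1	0	.
chr1	32380	32980	noise_H3K27ac_D0_WT_r1_1	0	.
chr1	49571	50144	peak0034_r1	0	.
chr1	71408	72003	peak0031_r1	0	.
chr1	77883	78501	peak0015_r1	0	.
chr1	99934	100558	peak0048_r1	0	.
chr1	110999	111598	peak0003_r1	0	.
chr1	130403	131027	peak0038_r1	0	.
chr1	132236	132841	peak0013_r1	0	.
chr1	143402	144007	peak0012_r1	0	.
chr1	176746	177346	noise_H3K27ac_D0_WT_r1_0	0	.
chr1	191427	192024	peak0029_r1	0	.
chr1	194448	195048	noise_H3K27ac_D0_WT_r1_2	0	.
chr2	18773	19354	peak0002_r1	0	.
chr2	41641	42241	peak0009_r1	0	.
chr2	47955	48542	peak0000_r1	0	.
chr2	67718	68336	peak0004_r1	0	.
chr2	76249	76835	peak0001_r1	0	.
chr2	88643	89246	peak0030_r1	0	.
chr2	91772	92372	noise_H3K27ac_D0_WT_r1_3	0	.
chr2	96195	96784	peak0010_r1	0	.
chr2	103227	103840	peak0037_r1	0	.
chr2	110636	111214	peak0028_r1	0	.
chr2	117673	118271	peak0049_r1	0	.
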