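chr1	11552	12564	peak0022_r3	0	.
chr1	20713	21708	peak0007_r3	0	.
chr1	64085	65085	noise_H3K27me3_D35_HET_r3_3	0	.
chr1	64157	65157	noise_H3K27me3_D35_HET_r3_1	0	.
chr1	72566	73569	peak0008_r3	0	.
chr1	116275	117275	noise_H3K27me3_D35_HET_r3_2	0	.
chr1	157370	158370	noise_H3K27me3_D35_HET_r3_0	0	.
chr1	181495	182505	peak0050_r3	0	.
chr2	3316	4286	peak0051_r3	0	.
chr2	47773	48768	peak0000_r3	0	.
chr2	67537	68524	peak0004_r3	0	.
chr2	117479	118462	peak0049_r3	0	.
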