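chrom	left_arm_end_kb	right_arm_start_kb	rate_left_cm_mb	rate_center_cm_mb	rate_right_cm_mb	chrom_size_bp
I	5803	13007	5.197	0.673	3.529	17247545
II	6828	14292	3.883	0.808	2.938	19935723
III	5849	11888	4.791	0.316	3.601	17877849
IV	8639	17108	1.447	0.520	3.615	25790997
V	6767	13852	3.697	0.270	2.531	22502457
X	9040	16070	3.047	0.879	1.339	21501900
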