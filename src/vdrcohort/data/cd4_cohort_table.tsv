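sample	vitd_nmol	total	downstream	exons	intergenic	introns	up_and_downstream	upstream	utr
1_VDR	80	3073	5.2	3.9	37.9	24.0	4.7	13.8	10.5
2_VDR	107	7118	5.6	4.5	28.2	26.3	5.1	17.0	13.2
3_VDR	76	5290	5.4	3.5	36.8	29.1	4.1	12.9	8.3
4_VDR	85	3059	5.1	4.0	37.3	22.3	4.7	15.6	11.0
5_VDR	75	4051	4.6	4.8	33.0	21.5	5.3	18.8	12.1
HB	29	1021	3.5	5.7	27.4	16.9	5.6	24.1	17.0
PD	32	200	1.0	3.0	61.7	21.4	0.5	7.0	5.5
SP	34	610	3.2	4.5	38.7	18.8	3.7	18.3	13.0
SR	22	573	3.5	4.9	39.7	17.7	4.0	18.5	11.7
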