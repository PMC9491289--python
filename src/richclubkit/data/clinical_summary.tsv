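variable	ocd_n	ocd_mean	ocd_sd	sib_n	sib_mean	sib_sd	hc_n	hc_mean	hc_sd	reported_F
age	28	36.8	9.2	8	37.8	13.2	28	40.6	11.0	0.99
education	28	13.6	3.4	8	12.3	2.4	28	12.2	2.8	1.55
disease_duration	28	22.7	11.3	8	0	0	28	0	0	66.5
ybocs_total	28	21.3	6.0	8	0.1	0.4	28	0	0	220
ybocs_obsessions	28	10.3	3.6	8	0.1	0.4	28	0	0	146
ybocs_compulsions	28	11.0	3.0	8	0	0	28	0	0	236
ocir_total	28	22.8	11.7	8	2.9	2.9	28	3.3	5.4	37.3
ocir_washing	28	3.0	3.6	8	0	0	28	0.4	0.7	7.97
ocir_checking	28	6.4	4.2	8	0.6	0.9	28	0.3	0.6	32.5
ocir_ordering	28	4.4	3.7	8	0.4	0.7	28	0.9	1.8	12.4
ocir_obsession	28	4.9	3.5	8	0.6	1.2	28	0.4	1.6	21.1
ocir_hoarding	28	1.8	2.6	8	1.1	1.4	28	1.2	2.2	0.4
ocir_neutralizing	28	2.1	3.0	8	0.1	0.4	28	0.1	0.2	7.46
madrs	28	9.3	6.9	8	1.3	2.9	28	1.0	1.6	20.6
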