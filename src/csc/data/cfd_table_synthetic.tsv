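kind	position	guide_base	site_base	pam	penalty
mismatch	1	A	C		0.76
mismatch	1	A	G		1.0
mismatch	1	A	T		0.76
mismatch	1	C	A		0.76
mismatch	1	C	G		0.76
mismatch	1	C	T		1.0
mismatch	1	G	A		1.0
mismatch	1	G	C		0.76
mismatch	1	G	T		0.76
mismatch	1	T	A		0.76
mismatch	1	T	C		1.0
mismatch	1	T	G		0.76
mismatch	2	A	C		0.7242
mismatch	2	A	G		1.0
mismatch	2	A	T		0.7242
mismatch	2	C	A		0.7242
mismatch	2	C	G		0.7242
mismatch	2	C	T		1.0
mismatch	2	G	A		1.0
mismatch	2	G	C		0.7242
mismatch	2	G	T		0.7242
mismatch	2	T	A		0.7242
mismatch	2	T	C		1.0
mismatch	2	T	G		0.7242
mismatch	3	A	C		0.6884
mismatch	3	A	G		0.9896
mismatch	3	A	T		0.6884
mismatch	3	C	A		0.6884
mismatch	3	C	G		0.6884
mismatch	3	C	T		0.9896
mismatch	3	G	A		0.9896
mismatch	3	G	C		0.6884
mismatch	3	G	T		0.6884
mismatch	3	T	A		0.6884
mismatch	3	T	C		0.9896
mismatch	3	T	G		0.6884
mismatch	4	A	C		0.6526
mismatch	4	A	G		0.9382
mismatch	4	A	T		0.6526
mismatch	4	C	A		0.6526
mismatch	4	C	G		0.6526
mismatch	4	C	T		0.9382
mismatch	4	G	A		0.9382
mismatch	4	G	C		0.6526
mismatch	4	G	T		0.6526
mismatch	4	T	A		0.6526
mismatch	4	T	C		0.9382
mismatch	4	T	G		0.6526
mismatch	5	A	C		0.6168
mismatch	5	A	G		0.8867
mismatch	5	A	T		0.6168
mismatch	5	C	A		0.6168
mismatch	5	C	G		0.6168
mismatch	5	C	T		0.8867
mismatch	5	G	A		0.8867
mismatch	5	G	C		0.6168
mismatch	5	G	T		0.6168
mismatch	5	T	A		0.6168
mismatch	5	T	C		0.8867
mismatch	5	T	G		0.6168
mismatch	6	A	C		0.5811
mismatch	6	A	G		0.8353
mismatch	6	A	T		0.5811
mismatch	6	C	A		0.5811
mismatch	6	C	G		0.5811
mismatch	6	C	T		0.8353
mismatch	6	G	A		0.8353
mismatch	6	G	C		0.5811
mismatch	6	G	T		0.5811
mismatch	6	T	A		0.5811
mismatch	6	T	C		0.8353
mismatch	6	T	G		0.5811
mismatch	7	A	C		0.5453
mismatch	7	A	G		0.7838
mismatch	7	A	T		0.5453
mismatch	7	C	A		0.5453
mismatch	7	C	G		0.5453
mismatch	7	C	T		0.7838
mismatch	7	G	A		0.7838
mismatch	7	G	C		0.5453
mismatch	7	G	T		0.5453
mismatch	7	T	A		0.5453
mismatch	7	T	C		0.7838
mismatch	7	T	G		0.5453
mismatch	8	A	C		0.5095
mismatch	8	A	G		0.7324
mismatch	8	A	T		0.5095
mismatch	8	C	A		0.5095
mismatch	8	C	G		0.5095
mismatch	8	C	T		0.7324
mismatch	8	G	A		0.7324
mismatch	8	G	C		0.5095
mismatch	8	G	T		0.5095
mismatch	8	T	A		0.5095
mismatch	8	T	C		0.7324
mismatch	8	T	G		0.5095
mismatch	9	A	C		0.4737
mismatch	9	A	G		0.6809
mismatch	9	A	T		0.4737
mismatch	9	C	A		0.4737
mismatch	9	C	G		0.4737
mismatch	9	C	T		0.6809
mismatch	9	G	A		0.6809
mismatch	9	G	C		0.4737
mismatch	9	G	T		0.4737
mismatch	9	T	A		0.4737
mismatch	9	T	C		0.6809
mismatch	9	T	G		0.4737
mismatch	10	A	C		0.4379
mismatch	10	A	G		0.6295
mismatch	10	A	T		0.4379
mismatch	10	C	A		0.4379
mismatch	10	C	G		0.4379
mismatch	10	C	T		0.6295
mismatch	10	G	A		0.6295
mismatch	10	G	C		0.4379
mismatch	10	G	T		0.4379
mismatch	10	T	A		0.4379
mismatch	10	T	C		0.6295
mismatch	10	T	G		0.4379
mismatch	11	A	C		0.4021
mismatch	11	A	G		0.578
mismatch	11	A	T		0.4021
mismatch	11	C	A		0.4021
mismatch	11	C	G		0.4021
mismatch	11	C	T		0.578
mismatch	11	G	A		0.578
mismatch	11	G	C		0.4021
mismatch	11	G	T		0.4021
mismatch	11	T	A		0.4021
mismatch	11	T	C		0.578
mismatch	11	T	G		0.4021
mismatch	12	A	C		0.3663
mismatch	12	A	G		0.5266
mismatch	12	A	T		0.3663
mismatch	12	C	A		0.3663
mismatch	12	C	G		0.3663
mismatch	12	C	T		0.5266
mismatch	12	G	A		0.5266
mismatch	12	G	C		0.3663
mismatch	12	G	T		0.3663
mismatch	12	T	A		0.3663
mismatch	12	T	C		0.5266
mismatch	12	T	G		0.3663
mismatch	13	A	C		0.3305
mismatch	13	A	G		0.4751
mismatch	13	A	T		0.3305
mismatch	13	C	A		0.3305
mismatch	13	C	G		0.3305
mismatch	13	C	T		0.4751
mismatch	13	G	A		0.4751
mismatch	13	G	C		0.3305
mismatch	13	G	T		0.3305
mismatch	13	T	A		0.3305
mismatch	13	T	C		0.4751
mismatch	13	T	G		0.3305
mismatch	14	A	C		0.2947
mismatch	14	A	G		0.4237
mismatch	14	A	T		0.2947
mismatch	14	C	A		0.2947
mismatch	14	C	G		0.2947
mismatch	14	C	T		0.4237
mismatch	14	G	A		0.4237
mismatch	14	G	C		0.2947
mismatch	14	G	T		0.2947
mismatch	14	T	A		0.2947
mismatch	14	T	C		0.4237
mismatch	14	T	G		0.2947
mismatch	15	A	C		0.2589
mismatch	15	A	G		0.3722
mismatch	15	A	T		0.2589
mismatch	15	C	A		0.2589
mismatch	15	C	G		0.2589
mismatch	15	C	T		0.3722
mismatch	15	G	A		0.3722
mismatch	15	G	C		0.2589
mismatch	15	G	T		0.2589
mismatch	15	T	A		0.2589
mismatch	15	T	C		0.3722
mismatch	15	T	G		0.2589
mismatch	16	A	C		0.2232
mismatch	16	A	G		0.3208
mismatch	16	A	T		0.2232
mismatch	16	C	A		0.2232
mismatch	16	C	G		0.2232
mismatch	16	C	T		0.3208
mismatch	16	G	A		0.3208
mismatch	16	G	C		0.2232
mismatch	16	G	T		0.2232
mismatch	16	T	A		0.2232
mismatch	16	T	C		0.3208
mismatch	16	T	G		0.2232
mismatch	17	A	C		0.1874
mismatch	17	A	G		0.2693
mismatch	17	A	T		0.1874
mismatch	17	C	A		0.1874
mismatch	17	C	G		0.1874
mismatch	17	C	T		0.2693
mismatch	17	G	A		0.2693
mismatch	17	G	C		0.1874
mismatch	17	G	T		0.1874
mismatch	17	T	A		0.1874
mismatch	17	T	C		0.2693
mismatch	17	T	G		0.1874
mismatch	18	A	C		0.1516
mismatch	18	A	G		0.2179
mismatch	18	A	T		0.1516
mismatch	18	C	A		0.1516
mismatch	18	C	G		0.1516
mismatch	18	C	T		0.2179
mismatch	18	G	A		0.2179
mismatch	18	G	C		0.1516
mismatch	18	G	T		0.1516
mismatch	18	T	A		0.1516
mismatch	18	T	C		0.2179
mismatch	18	T	G		0.1516
mismatch	19	A	C		0.1158
mismatch	19	A	G		0.1664
mismatch	19	A	T		0.1158
mismatch	19	C	A		0.1158
mismatch	19	C	G		0.1158
mismatch	19	C	T		0.1664
mismatch	19	G	A		0.1664
mismatch	19	G	C		0.1158
mismatch	19	G	T		0.1158
mismatch	19	T	A		0.1158
mismatch	19	T	C		0.1664
mismatch	19	T	G		0.1158
mismatch	20	A	C		0.08
mismatch	20	A	G		0.115
mismatch	20	A	T		0.08
mismatch	20	C	A		0.08
mismatch	20	C	G		0.08
mismatch	20	C	T		0.115
mismatch	20	G	A		0.115
mismatch	20	G	C		0.08
mismatch	20	G	T		0.08
mismatch	20	T	A		0.08
mismatch	20	T	C		0.115
mismatch	20	T	G		0.08
pam	0			AAG	0.25
pam	0			AGA	0.05
pam	0			AGG	1.0
pam	0			CAG	0.25
pam	0			CGA	0.05
pam	0			CGG	1.0
pam	0			GAG	0.25
pam	0			GGA	0.05
pam	0			GGG	1.0
pam	0			TAG	0.25
pam	0			TGA	0.05
pam	0			TGG	1.0
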