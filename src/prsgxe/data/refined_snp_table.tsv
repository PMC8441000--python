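snp_id	chrom	pos	effect_allele	other_allele	beta	p_value
rs7574670	0	1	A	G	1.0	0.000123
rs13225097	0	2	A	G	1.0	0.000846
rs196808	0	3	A	G	1.0	0.005017
rs6885750	0	4	A	G	1.0	0.010573
rs4841679	0	5	A	G	1.0	0.011172
rs870870	0	6	A	G	1.0	0.018874
rs2665316	0	7	A	G	1.0	0.019226
rs4405319	0	8	A	G	1.0	0.031478
rs11724118	0	9	A	G	1.0	0.045920
rs10804992	0	10	A	G	1.0	0.046243
rs6552502	0	11	A	G	1.0	0.058479
rs397234	0	12	A	G	1.0	0.058594
rs11898925	0	13	A	G	1.0	0.061942
rs1866816	0	14	A	G	1.0	0.061986
rs7807790	0	15	A	G	1.0	0.062096
rs2965106	0	16	A	G	1.0	0.062112
rs275146	0	17	A	G	1.0	0.062816
rs7155790	0	18	A	G	1.0	0.065848
rs9840453	0	19	A	G	1.0	0.067170
rs11693862	0	20	A	G	1.0	0.073821
rs1492377	0	21	A	G	1.0	0.074815
rs1377315	0	22	A	G	1.0	0.083513
rs4686837	0	23	A	G	1.0	0.088538
rs4803789	0	24	A	G	1.0	0.089959
rs10520768	0	25	A	G	1.0	0.090182
rs2295308	0	26	A	G	1.0	0.093524
rs7598551	0	27	A	G	1.0	0.094168
rs7332334	0	28	A	G	1.0	0.101271
rs728586	0	29	A	G	1.0	0.103540
rs4779876	0	30	A	G	1.0	0.103930
rs1935492	0	31	A	G	1.0	0.103989
rs7983099	0	32	A	G	1.0	0.112130
rs923554	0	33	A	G	1.0	0.118880
rs1885414	0	34	A	G	1.0	0.123295
rs9863801	0	35	A	G	1.0	0.126196
rs11891202	0	36	A	G	1.0	0.135653
rs4382157	0	37	A	G	1.0	0.136635
rs5753103	0	38	A	G	1.0	0.150747
rs17035960	0	39	A	G	1.0	0.151128
rs884972	0	40	A	G	1.0	0.151753
rs10002944	0	41	A	G	1.0	0.154237
rs10145606	0	42	A	G	1.0	0.156256
rs892114	0	43	A	G	1.0	0.159405
rs6543408	0	44	A	G	1.0	0.178625
rs4766912	0	45	A	G	1.0	0.184907
rs7138803	0	46	A	G	1.0	0.185122
rs2544164	0	47	A	G	1.0	0.197849
rs12219445	0	48	A	G	1.0	0.198058
rs1664256	0	49	A	G	1.0	0.199221
rs11603179	0	50	A	G	1.0	0.201429
rs11820303	0	51	A	G	1.0	0.211331
rs2341647	0	52	A	G	1.0	0.217823
rs6888754	0	53	A	G	1.0	0.219617
rs9808140	0	54	A	G	1.0	0.221567
rs1058065	0	55	A	G	1.0	0.223190
rs12731669	0	56	A	G	1.0	0.231006
rs7243066	0	57	A	G	1.0	0.238047
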