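chrom	start	end	length	n_snps
2	81496310	81511148	14838	273
3	11716513	11776690	60177	452
4	105573863	105589511	15648	1422
4	112830880	113341416	510536	13917
5	92617024	92629684	12660	236
6	55737025	55758674	21649	508
7	10758277	11039089	280812	4584
7	95736166	95742201	6035	163
8	29160922	29183317	22395	559
9	10593065	10596144	3079	59
9	104358861	104380205	21344	671
10	459493	521352	61859	846
10	22908467	23406397	497930	2334
10	100209890	101216542	1006652	2146
11	40903028	40905284	2256	72
12	70443588	70455007	11419	713
12	71728153	71735710	7557	719
14	82178440	82180992	2552	60
15	45854158	46106343	252185	3506
15	78379540	79226472	846932	398
16	372932	418633	45701	1473
16	5775482	5778367	2885	53
17	14049911	14159496	109585	4297
17	37810468	39363461	1552993	4880
18	62688950	62690650	1700	5
19	927489	945870	18381	537
20	49746665	49760276	13611	432
22	897334	922574	25240	738
23	15964918	15976090	11172	138
23	25875394	26511965	636571	2223
29	51092637	51093495	858	23
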