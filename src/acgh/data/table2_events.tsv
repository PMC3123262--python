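No	Type	Chr	Start	End	Length	Log R	Shared
1	Self1	chr13	48,998,999	49,016,999	18,000	0.5168	Yes
1	Self1	chr3	1,020,294	1,039,699	19,405	0.6721	Yes
1	Self1	chr4	41,465,452	41,496,569	31,117	0.6946	Yes
2	High1	chr13	48,992,999	49,010,999	18,000	0.6269	Yes
2	High1	chr3	1,020,294	1,039,699	19,405	0.6410	Yes
2	High1	chr4	33,570,495	33,584,300	13,805	0.5216	Yes
2	High1	chr4	41,465,452	41,496,569	31,117	0.5674	Yes
3	Low1	chr13	48,991,360	49,017,997	26,637	0.6818	Yes
3	Low1	chr29	19,400,430	19,449,274	48,844	0.5343	Yes
3	Low1	chr3	1,020,294	1,042,839	22,545	0.7566	Yes
3	Low1	chr4	41,465,452	41,496,569	31,117	0.8130	Yes
4	Self2	chr13	48,991,360	49,017,997	26,637	0.5172	Yes
4	Self2	chr3	1,020,294	1,042,839	22,545	0.6039	Yes
4	Self2	chr4	41,465,452	41,496,569	31,117	0.5761	Yes
5	High2	chr25	32,373,045	32,464,814	91,769	0.6769	Yes
6	Low2	chr11	87,532,580	87,543,090	10,510	-0.5617	No
6	Low2	chr2	16,958,057	16,968,620	10,563	-0.5814	No
6	Low2	chr25	32,374,157	32,471,634	97,477	-0.8136	Yes
6	Low2	chr29	43,204,051	43,223,301	19,250	-0.5334	No
6	Low2	chrX	10,447,331	10,457,486	10,155	-0.9137	No
7	Self3	chr1	5,249,999	5,285,999	36,000	0.5481	Yes
7	Self3	chr10	59,478,526	59,531,204	52,678	0.5501	No
7	Self3	chr13	48,991,360	49,017,997	26,637	0.6809	Yes
7	Self3	chr15	26,576,999	26,602,199	25,200	0.6474	Yes
7	Self3	chr2	39,223,655	39,235,168	11,513	-0.5661	No
7	Self3	chr25	32,374,157	32,471,634	97,477	-0.6113	Yes
7	Self3	chr29	19,399,250	19,449,274	50,024	0.6094	Yes
7	Self3	chr3	1,020,294	1,039,699	19,405	0.8678	Yes
7	Self3	chr4	27,707,990	27,750,008	42,018	0.5614	No
7	Self3	chr4	41,465,452	41,496,569	31,117	0.8426	Yes
7	Self3	chr6	45,738,703	45,776,348	37,645	0.5049	Yes
7	Self3	chr6	89,209,799	89,220,599	10,800	0.6477	Yes
7	Self3	chr8	36,073,799	36,145,799	72,000	0.5122	Yes
7	Self3	chrX	37,290,568	37,303,155	12,587	0.8150	No
7	Self3	chrX	37,564,199	37,614,599	50,400	0.5427	No
7	Self3	chrX	56,120,456	56,149,298	28,842	0.6124	No
7	Self3	chrX	84,230,177	84,255,543	25,366	0.5679	No
7	Self3	chrX	138,374,999	138,386,999	12,000	0.5528	No
8	High3	chr13	48,993,325	49,013,328	20,003	0.5149	Yes
8	High3	chr15	26,576,999	26,602,199	25,200	0.6022	Yes
8	High3	chr25	32,374,157	32,403,637	29,480	-0.8278	Yes
8	High3	chr4	33,564,599	33,578,999	14,400	0.5363	Yes
8	High3	chr4	41,466,599	41,495,399	28,800	0.5097	Yes
8	High3	chr6	45,744,065	45,772,999	28,934	0.5284	Yes
9	Low3	chr1	5,249,999	5,285,999	36,000	0.5559	Yes
9	Low3	chr1	144,107,850	144,130,905	23,055	0.5949	No
9	Low3	chr13	48,991,360	49,017,997	26,637	0.6031	Yes
9	Low3	chr17	73,139,605	73,159,081	19,476	-2.0603	No
9	Low3	chr18	6,080,815	6,121,152	40,337	-0.5749	No
9	Low3	chr25	32,362,844	32,470,747	107,903	0.6669	Yes
9	Low3	chr29	19,412,812	19,444,215	31,403	0.6690	Yes
9	Low3	chr3	1,020,599	1,038,599	18,000	0.6787	Yes
9	Low3	chr4	33,564,599	33,578,999	14,400	0.6100	Yes
9	Low3	chr4	41,465,452	41,487,890	22,438	0.6229	Yes
9	Low3	chr6	89,208,198	89,218,288	10,090	0.6937	Yes
9	Low3	chr8	36,077,399	36,152,999	75,600	0.5089	Yes
9	Low3	chrU	12,620,478	12,665,758	45,280	0.7441	No
10	Self4	chr13	48,992,999	49,010,999	18,000	0.5729	Yes
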