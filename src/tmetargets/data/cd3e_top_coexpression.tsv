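rank	symbol	median_r	panel
1	CD2	0.955	1
2	CD247	0.944	0
3	SIRPG	0.942	0
4	CD3D	0.933	0
5	LCK	0.918	0
6	SIT1	0.917	0
7	CD6	0.912	0
8	CXCR3	0.910	0
9	SH2D1A	0.907	0
10	SLA2	0.904	0
11	SLAMF6	0.902	0
12	ITGAL	0.897	0
13	TIGIT	0.896	1
14	CD96	0.896	0
15	TRAF3IP3	0.892	0
16	ACAP1	0.882	0
17	RASAL3	0.882	0
18	ITK	0.879	0
19	TBC1D10C	0.879	0
20	CD27	0.877	1
21	CD48	0.872	0
22	GZMK	0.870	0
23	SASH3	0.865	0
24	LY9	0.865	0
25	SEPT1	0.865	0
26	PTPRCAP	0.862	0
27	ARHGAP9	0.858	0
28	CD3G	0.857	0
29	TESPA1	0.856	0
30	MAP4K1	0.854	0
31	CORO1A	0.842	0
32	SLAMF1	0.841	0
33	NLRC3	0.839	0
34	CST7	0.838	0
35	IL2RG	0.838	0
36	WAS	0.837	0
37	CD8A	0.834	0
38	CD5	0.829	0
39	GIMAP5	0.828	0
40	IKZF1	0.828	0
41	ZAP70	0.828	0
42	KLRK1	0.827	0
43	CCL5	0.827	0
44	GPR171	0.826	0
45	PVRIG	0.825	0
46	PTPN7	0.824	0
47	CXCR6	0.823	0
48	EVI2B	0.823	0
49	CCR5	0.819	0
50	GZMA	0.815	0
51	ICOS	0.815	1
52	GRAP2	0.813	0
53	PTPRC	0.808	0
54	GIMAP4	0.806	0
55	PDCD1	0.806	1
103	CTLA4	0.727	1
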