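probe_id	fold_change	p_value	gene_symbol	accession
TC0500008318.hg.1	-2.37	0.0026	EPB41L4A-AS1	ENST00000413221.2
TC0700007000.hg.1	-2.02	0.0015	HOTAIRM1	ENST00000616712
TC0600008510.hg.1	-2.25	0.0087	KCNQ5-IT1	ENST00000445310
TC0700013567.hg.1	2.05	0.0013	LINC00174	ENST00000416366
TC0700007277.hg.1	2.46	0.0001	LINC00265	ENST00000340510.4
TC1500007707.hg.1	-1.58	0.0089	LINC00593	ENST00000558385.1
TC2000008995.hg.1	-2.27	0.0017	LINC00657	ENST00000565493
TC1800009043.hg.1	-1.84	0.0025	LINC00909	ENST00000577806
TC0200007199.hg.1	2.27	0.0007	LINC00486	ENST00000414054
TC0100009691.hg.1	-1.97	0.0003	RP11-403I13.5	ENST00000443018.1
TC0200010127.hg.1	-3.24	<0.0001	RP11-171I2.4	ENST00000605334.1
TC0200011420.hg.1	-2.68	0.0005	AC133528.2	ENST00000433036.1
TC0400009914.hg.1	-2.37	0.0027	RP11-539L10.3	ENST00000513179.1
TC0500009465.hg.1	-1.74	0.007	RP11-779O18.3	ENST00000523005.1
TC0800007847.hg.1	-14.9	<0.0001	AC084082.3	ENST00000517961.2
TC1100011278.hg.1	1.91	0.0003	RP11-867G23.3	ENST00000501708.1
TC1200006772.hg.1	-1.86	0.0044	RP11-75L1.1	ENST00000541404.1
TC1200010732.hg.1	-3.11	0.0058	RP11-1100L3.8	ENST00000564363.1
TC1400006719.hg.1	-2.54	0.0066	RP11-468E2.5	ENST00000558478.1
TC1400009275.hg.1	-1.61	0.0027	RP11-930O11.2	ENST00000560296.1
TC1600009188.hg.1	2.21	0.0021	LA16c-360H6.3	ENST00000574245.1
TC1700007241.hg.1	2.64	0.0008	RP11-283C24.1	ENST00000578585.1
TC2100007843.hg.1	-1.78	0.0016	AF131217.1	ENST00000430247.1
TC2200008462.hg.1	-3.38	0.0058	RP3-430N8.10	ENST00000602955.1
TC1500010312.hg.1	-2.52	0.0064	RP11-815J21.2	ENST00000561409.1
TC1800007426.hg.1	-3.49	0.0032	RP11-1151B14.4	ENST00000591360.1
TC1900011833.hg.1	1.81	0.0031	CTB-25B13.12	ENST00000588225.1
TC1900007159.hg.1	-1.77	0.0084	CTB-55O6.10	ENST00000590715.1
TC1200008393.hg.1	-1.74	0.0028	RP11-981P6.1	ENST00000552778.1
TC1200008425.hg.1	-2.1	0.0024	RP11-796E2.4	ENST00000499685.2
TC1400009962.hg.1	-2.61	0.0006	RP11-471B22.2	ENST00000555853.1
TC1600006833.hg.1	2.16	0.0024	RP11-77H9.5	ENST00000564919.1
TC1400009667.hg.1	1.88	0.0092	RP4-693M11.3	ENST00000557304.1
TC1000009009.hg.1	-1.6	0.0098	RP11-498B4.5	ENST00000433600.1
TC1400010386.hg.1	1.71	0.0064	CTD-3051D23.4	ENST00000553344.2
TC1200008527.hg.1	-2.91	0.0065	RP11-256L6.3	ENST00000551849.1
TC0200007485.hg.1	1.61	0.0048	AC016722.4	ENST00000429761.1
TC1400007302.hg.1	1.95	0.0041	CTD-2002H8.2	ENST00000557322.1
TC0500008150.hg.1	-2.4	0.0066	CTD-2260A17.1	ENST00000512856.1
TC0600010636.hg.1	-1.89	0.0005	RP3-406P24.3	ENST00000415144.1
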