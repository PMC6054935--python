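lncrna	target	target_class
LINC00174	CPSF7	gene
LINC00265	IGF2BP2	gene
LINC00593	UPF1	gene
LINC00657	CPSF7	gene
LINC00657	FXR1	gene
LINC00657	HNRNPC	gene
LINC00657	NUDT21	gene
LINC00657	UPF1	gene
LINC00657	ZC3H7B	gene
LINC00657	hsa-miR-130a-3p	mirna
LINC00657	hsa-miR-17-5p	mirna
LINC00657	hsa-miR-186-5p	mirna
LINC00657	hsa-miR-199a-3p	mirna
LINC00657	hsa-miR-199a-5p	mirna
LINC00657	hsa-miR-28-5p	mirna
LINC00657	hsa-miR-320c	mirna
LINC00657	hsa-miR-320d	mirna
LINC00657	hsa-miR-331-3p	mirna
LINC00657	hsa-miR-423-5p	mirna
LINC00657	hsa-miR-451a	mirna
LINC00909	UPF1	gene
LINC00909	hsa-miR-130a-3p	mirna
LINC00909	hsa-miR-148a-3p	mirna
LINC00909	hsa-miR-28-5p	mirna
LINC00909	hsa-miR-320c	mirna
LINC00909	hsa-miR-320d	mirna
LINC00486	FXR1	gene
LINC00486	UPF1	gene
EPB41L4A-AS1	CPSF7	gene
EPB41L4A-AS1	UPF1	gene
EPB41L4A-AS1	hsa-miR-130a-3p	mirna
EPB41L4A-AS1	hsa-miR-17-5p	mirna
HOTAIRM1	CPSF7	gene
HOTAIRM1	UPF1	gene
KCNQ5-IT1	CPSF7	gene
KCNQ5-IT1	UPF1	gene
RP11-403I13.5	hsa-miR-92a-3p	mirna
RP11-171I2.4	CPSF7	gene
AC133528.2	CPSF7	gene
RP11-539L10.3	hsa-miR-148a-3p	mirna
RP11-539L10.3	hsa-miR-199a-3p	mirna
RP11-779O18.3	HNRNPC	gene
RP11-779O18.3	UPF1	gene
RP11-779O18.3	ZC3H7B	gene
AC084082.3	CPSF7	gene
AC084082.3	NUDT21	gene
AC084082.3	UPF1	gene
AC084082.3	hsa-miR-331-3p	mirna
RP11-867G23.3	UPF1	gene
RP11-867G23.3	IGF2BP2	gene
RP11-75L1.1	UPF1	gene
RP11-1100L3.8	UPF1	gene
RP11-1100L3.8	hsa-miR-17-5p	mirna
RP11-1100L3.8	hsa-miR-423-5p	mirna
RP11-468E2.5	UPF1	gene
RP11-930O11.2	UPF1	gene
LA16c-360H6.3	IGF2BP2	gene
LA16c-360H6.3	hsa-miR-17-5p	mirna
RP11-283C24.1	UPF1	gene
AF131217.1	UPF1	gene
RP3-430N8.10	hsa-miR-331-3p	mirna
RP11-815J21.2	hsa-miR-186-5p	mirna
RP11-1151B14.4	UPF1	gene
CTB-25B13.12	UPF1	gene
CTB-55O6.10	CPSF7	gene
CTB-55O6.10	UPF1	gene
RP11-981P6.1	CPSF7	gene
RP11-981P6.1	UPF1	gene
RP11-981P6.1	ZC3H7B	gene
RP11-796E2.4	UPF1	gene
RP11-796E2.4	hsa-miR-3135b	mirna
RP11-471B22.2	CPSF7	gene
RP11-471B22.2	IGF2BP2	gene
RP11-471B22.2	UPF1	gene
RP11-471B22.2	ZC3H7B	gene
RP11-77H9.5	CPSF7	gene
RP11-77H9.5	HNRNPC	gene
RP11-77H9.5	IGF2BP2	gene
RP11-77H9.5	UPF1	gene
RP4-693M11.3	UPF1	gene
RP11-498B4.5	UPF1	gene
CTD-3051D23.4	IGF2BP2	gene
RP11-256L6.3	NUDT21	gene
RP11-256L6.3	UPF1	gene
AC016722.4	CPSF7	gene
AC016722.4	UPF1	gene
AC016722.4	ZC3H7B	gene
CTD-2002H8.2	CPSF7	gene
CTD-2002H8.2	HNRNPC	gene
CTD-2002H8.2	NUDT21	gene
CTD-2002H8.2	UPF1	gene
CTD-2002H8.2	ZC3H7B	gene
CTD-2260A17.1	hsa-miR-151a-5p	mirna
RP3-406P24.3	CPSF7	gene
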