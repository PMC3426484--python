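statistic	sub_pathway	gene	continental_group	p_value	corrected_p
FST	Branching 1	MAN2A2	CSASIA	3e-12	4.2e-11
FST	Branching 1	MGAT3	CSASIA	2e-8	2.8e-7
FST	Branching 2	B4GALT2	MENA	2e-7	2.8e-6
FST	Branching 2	MGAT4A	EUR	3e-6	4.2e-5
FST	Branching 2	MGAT4A	EASIA	3e-6	4.2e-5
FST	Branching 2	ST3GAL4	SSAFR	3e-7	4.2e-6
FST	Branching 2	ST8SIA3	EUR	2e-7	2.8e-6
FST	Branching 2	ST8SIA6	CSASIA	3e-6	4.2e-5
FST	Substrates	DPM1	MENA	3e-8	4.2e-7
FST	Substrates	DPM3	CSASIA	2e-24	2.8e-23
FST	Substrates	PMM1	EASIA	8e-7	1.1e-5
ABS_IHS	Precursor Biosynthesis	ALG12	MENA	3e-10	4.2e-9
ABS_IHS	Precursor Biosynthesis	ALG12	EUR	1e-10	1.4e-9
ABS_IHS	Precursor Biosynthesis	ALG12	EASIA	5e-11	7.0e-10
ABS_IHS	Precursor Biosynthesis	GANAB	SSAFR	4e-7	5.6e-6
ABS_IHS	CNX_CRT	EDEM3	OCE	1e-10	1.4e-9
ABS_IHS	CNX_CRT	GCS1	MENA	2e-14	2.8e-13
ABS_IHS	CNX_CRT	GCS1	EUR	2e-16	2.8e-15
ABS_IHS	CNX_CRT	GCS1	CSASIA	2e-6	2.8e-5
ABS_IHS	CNX_CRT	UGCGL2	SSAFR	4e-5	5.6e-4
ABS_IHS	Branching 1	FUT8	SSAFR	1e-4	1.4e-3
ABS_IHS	Branching 1	MAN1A1	AME	5e-13	7.0e-12
ABS_IHS	Branching 1	MAN1A2	SSAFR	8e-4	1.12e-2
ABS_IHS	Branching 1	MAN2A1	SSAFR	4e-23	5.6e-22
ABS_IHS	Branching 1	MAN2A1	EASIA	3e-10	4.2e-9
ABS_IHS	Branching 1	MGAT2	EASIA	4e-7	5.6e-6
ABS_IHS	Branching 1	MGAT3	EASIA	1e-14	1.4e-13
ABS_IHS	Branching 2	MGAT5B	MENA	1e-7	1.4e-6
ABS_IHS	Branching 2	MGAT5B	EUR	7e-8	9.8e-7
ABS_IHS	Branching 2	ST8SIA3	MENA	5e-10	7.0e-9
ABS_IHS	Branching 2	ST8SIA3	EUR	2e-8	2.8e-7
ABS_IHS	Substrates	DPM1	MENA	5e-12	7.0e-11
ABS_IHS	Substrates	DPM1	EUR	1e-8	1.4e-7
ABS_IHS	Substrates	DPM1	CSASIA	2e-16	2.8e-15
ABS_IHS	Substrates	DOLPP1	CSASIA	2e-5	2.8e-4
ABS_IHS	Substrates	DPM2	EUR	5e-7	7.0e-6
ABS_IHS	Substrates	DPM3	EASIA	6e-30	8.4e-29
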