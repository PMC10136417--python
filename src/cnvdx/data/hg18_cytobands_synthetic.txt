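chr1	0	2300000	p36.33	gneg
chr1	2300000	12000000	p36.2	gpos25
chr1	12000000	28000000	p35	gpos50
chr1	28000000	40000000	p34	gpos75
chr1	40000000	50000000	p33	gneg
chr1	50000000	60000000	p32	gpos25
chr1	60000000	84000000	p31	gpos50
chr1	84000000	94000000	p22	gpos75
chr1	94000000	107000000	p21	gneg
chr1	107000000	117000000	p13	gpos25
chr1	117000000	120000000	p12	gpos50
chr1	120000000	125000000	p11	gpos75
chr1	125000000	144000000	q11	gneg
chr1	144000000	173000000	q21	gpos25
chr1	173000000	205000000	q31	gpos50
chr1	205000000	222000000	q41	gpos75
chr1	222000000	235000000	q42	gneg
chr1	235000000	243000000	q43	gpos25
chr1	243000000	247249719	q44	gpos50
chr3	0	8000000	p26	gneg
chr3	8000000	16000000	p25	gpos25
chr3	16000000	30000000	p24	gpos50
chr3	30000000	33000000	p23	gpos75
chr3	33000000	40000000	p22	gneg
chr3	40000000	52000000	p21	gpos25
chr3	52000000	57000000	p14.3	gpos50
chr3	57000000	60000000	p14.2	gpos75
chr3	60000000	65000000	p14.1	gneg
chr3	65000000	71000000	p13	gpos25
chr3	71000000	87000000	p12	gpos50
chr3	87000000	91000000	p11	gpos75
chr3	91000000	98000000	q11	gneg
chr3	98000000	115000000	q13	gpos25
chr3	115000000	130000000	q21	gpos50
chr3	130000000	145000000	q24	gpos75
chr3	145000000	170000000	q26	gneg
chr3	170000000	185000000	q27	gpos25
chr3	185000000	199501827	q29	gpos50
chr8	0	12000000	p23	gneg
chr8	12000000	19000000	p22	gpos25
chr8	19000000	30000000	p21	gpos50
chr8	30000000	39000000	p12	gpos75
chr8	39000000	45000000	p11	gneg
chr8	45000000	55000000	q11	gpos25
chr8	55000000	78000000	q21	gpos50
chr8	78000000	93000000	q22	gpos75
chr8	93000000	110000000	q23	gneg
chr8	110000000	128000000	q24.1	gpos25
chr8	128000000	140000000	q24.2	gpos50
chr8	140000000	146274826	q24.3	gpos75
chr9	0	2500000	p24.3	gneg
chr9	2500000	4000000	p24.2	gpos25
chr9	4000000	9000000	p24.1	gpos50
chr9	9000000	14000000	p23	gpos75
chr9	14000000	19000000	p22	gneg
chr9	19000000	28000000	p21	gpos25
chr9	28000000	34000000	p13.3	gpos50
chr9	34000000	38000000	p13.2	gpos75
chr9	38000000	40000000	p13.1	gneg
chr9	40000000	43000000	p12	gpos25
chr9	43000000	49000000	p11	gpos50
chr9	49000000	65000000	q11	gpos75
chr9	65000000	90000000	q21	gneg
chr9	90000000	110000000	q31	gpos25
chr9	110000000	130000000	q33	gpos50
chr9	130000000	140273252	q34	gpos75
chr10	0	6000000	p15	gneg
chr10	6000000	18000000	p13	gpos25
chr10	18000000	30000000	p12	gpos50
chr10	30000000	40000000	p11	gpos75
chr10	40000000	52000000	q11	gneg
chr10	52000000	70000000	q21	gpos25
chr10	70000000	82000000	q22	gpos50
chr10	82000000	95000000	q23	gpos75
chr10	95000000	105000000	q24	gneg
chr10	105000000	119000000	q25	gpos25
chr10	119000000	123000000	q26.11	gpos50
chr10	123000000	126000000	q26.12	gpos75
chr10	126000000	129000000	q26.13	gneg
chr10	129000000	133000000	q26.2	gpos25
chr10	133000000	135374737	q26.3	gpos50
chr11	0	2500000	p15.5	gneg
chr11	2500000	7000000	p15.4	gpos25
chr11	7000000	10000000	p15.3	gpos50
chr11	10000000	12500000	p15.2	gpos75
chr11	12500000	16000000	p15.1	gneg
chr11	16000000	27000000	p14	gpos25
chr11	27000000	31000000	p13	gpos50
chr11	31000000	36000000	p12	gpos75
chr11	36000000	48000000	p11	gneg
chr11	48000000	53000000	q11	gpos25
chr11	53000000	59000000	q12.1	gpos50
chr11	59000000	62000000	q12.2	gpos75
chr11	62000000	63500000	q12.3	gneg
chr11	63500000	66000000	q13.1	gpos25
chr11	66000000	68500000	q13.2	gpos50
chr11	68500000	71000000	q13.3	gpos75
chr11	71000000	74000000	q13.4	gneg
chr11	74000000	77000000	q13.5	gpos25
chr11	77000000	90000000	q14	gpos50
chr11	90000000	95000000	q21	gpos75
chr11	95000000	103000000	q22	gneg
chr11	103000000	112000000	q23	gpos25
chr11	112000000	122000000	q24.1	gpos50
chr11	122000000	125000000	q24.2	gpos75
chr11	125000000	130000000	q24.3	gneg
chr11	130000000	134452384	q25	gpos25
chr13	0	6000000	p13	gneg
chr13	6000000	16000000	p11	gpos25
chr13	16000000	18000000	q11	gpos50
chr13	18000000	28000000	q12	gpos75
chr13	28000000	35000000	q13	gneg
chr13	35000000	50000000	q14	gpos25
chr13	50000000	59000000	q21.1	gpos50
chr13	59000000	62000000	q21.2	gpos75
chr13	62000000	67000000	q21.3	gneg
chr13	67000000	75000000	q22	gpos25
chr13	75000000	90000000	q31	gpos50
chr13	90000000	97000000	q32.1	gpos75
chr13	97000000	99000000	q32.2	gneg
chr13	99000000	108000000	q33	gpos25
chr13	108000000	114142980	q34	gpos50
chr15	0	8000000	p13	gneg
chr15	8000000	17000000	p11	gpos25
chr15	17000000	20000000	q11	gpos50
chr15	20000000	23000000	q12	gpos75
chr15	23000000	28500000	q13.1	gneg
chr15	28500000	29500000	q13.2	gpos25
chr15	29500000	31000000	q13.3	gpos50
chr15	31000000	38000000	q14	gpos75
chr15	38000000	43000000	q15	gneg
chr15	43000000	55000000	q21	gpos25
chr15	55000000	65000000	q22	gpos50
chr15	65000000	70000000	q23	gpos75
chr15	70000000	77000000	q24	gneg
chr15	77000000	80000000	q25.1	gpos25
chr15	80000000	83000000	q25.2	gpos50
chr15	83000000	88000000	q25.3	gpos75
chr15	88000000	92000000	q26.1	gneg
chr15	92000000	96500000	q26.2	gpos25
chr15	96500000	100338915	q26.3	gpos50
chr16	0	7000000	p13.3	gneg
chr16	7000000	10000000	p13.2	gpos25
chr16	10000000	15000000	p13.1	gpos50
chr16	15000000	24000000	p12	gpos75
chr16	24000000	34500000	p11.2	gneg
chr16	34500000	38000000	p11.1	gpos25
chr16	38000000	47000000	q11	gpos50
chr16	47000000	54000000	q12	gpos75
chr16	54000000	58000000	q13	gneg
chr16	58000000	68000000	q21	gpos25
chr16	68000000	74000000	q22	gpos50
chr16	74000000	76000000	q23.1	gpos75
chr16	76000000	78000000	q23.2	gneg
chr16	78000000	81000000	q23.3	gpos25
chr16	81000000	88827254	q24	gpos50
chr18	0	3000000	p11.32	gneg
chr18	3000000	7000000	p11.31	gpos25
chr18	7000000	9000000	p11.23	gpos50
chr18	9000000	13000000	p11.22	gpos75
chr18	13000000	15300000	p11.21	gneg
chr18	15300000	16100000	p11.1	gpos25
chr18	16100000	19000000	q11.1	gpos50
chr18	19000000	25000000	q11.2	gpos75
chr18	25000000	39000000	q12	gneg
chr18	39000000	56000000	q21	gpos25
chr18	56000000	71000000	q22	gpos50
chr18	71000000	76117153	q23	gpos75
chr20	0	5000000	p13	gneg
chr20	5000000	12000000	p12	gpos25
chr20	12000000	27500000	p11	gpos50
chr20	27500000	30000000	q11.1	gpos75
chr20	30000000	34000000	q11.2	gneg
chr20	34000000	38000000	q12	gpos25
chr20	38000000	49000000	q13.1	gpos50
chr20	49000000	53000000	q13.2	gpos75
chr20	53000000	62435964	q13.3	gneg
chr22	0	4000000	p13	gneg
chr22	4000000	8000000	p12	gpos25
chr22	8000000	14000000	p11	gpos50
chr22	14000000	16000000	q11.1	gpos75
chr22	16000000	20000000	q11.21	gneg
chr22	20000000	22000000	q11.22	gpos25
chr22	22000000	24000000	q11.23	gpos50
chr22	24000000	31000000	q12	gpos75
chr22	31000000	38000000	q13.1	gneg
chr22	38000000	43000000	q13.2	gpos25
chr22	43000000	46000000	q13.31	gpos50
chr22	46000000	48000000	q13.32	gpos75
chr22	48000000	49691432	q13.33	gneg
chrX	0	4500000	p22.33	gneg
chrX	4500000	17000000	p22.2	gpos25
chrX	17000000	25000000	p22.1	gpos50
chrX	25000000	37000000	p21	gpos75
chrX	37000000	44000000	p11.4	gneg
chrX	44000000	47000000	p11.3	gpos25
chrX	47000000	57000000	p11.2	gpos50
chrX	57000000	60000000	p11.1	gpos75
chrX	60000000	63000000	q11.1	gneg
chrX	63000000	66000000	q12	gpos25
chrX	66000000	77000000	q13	gpos50
chrX	77000000	97000000	q21	gpos75
chrX	97000000	108000000	q22	gneg
chrX	108000000	115000000	q23	gpos25
chrX	115000000	122000000	q24	gpos50
chrX	122000000	130000000	q25	gpos75
chrX	130000000	138000000	q26	gneg
chrX	138000000	147000000	q27	gpos25
chrX	147000000	154913754	q28	gpos50
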