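chrom	start	end	length_kb	ltr_retrotransposon	line	dna_transposon	other_repeat	genes	grh_overlap
chrI	226000	239000	13	Cer13 fragment (656 bp) with homology to the PAO family retrotransposon integrase; no LTR at this target	-	-	-	Y48G1BM.5,Y48G1BM.6,Y48G1BM.7	+
chrI	4456000	4464000	8	-	-	-	Two ~930 bp DNA repeats 1.9 kb apart, 99% identical (chrI:4456382-4457314 and chrI:4459215-4460136); one contains the eri-6/eri-7 promoter	eri-7,eri-6,C41D11.6,T01A4.3	+
chrI	11438000	11449000	11	Cer16-2 (9.3 kb) with LTR in both ends	-	-	-	C27C7.1	+
chrII	2150000	2163000	13	Cer9-1 (9.5 kb) with LTR in both ends	-	-	-	C40A11.8,math-18	+
chrII	2516000	2521000	5	-	-	-	Two ~430 bp DNA repeats 3.5 kb apart, 98% identical (chrII:2520235-2520670 and chrII:2516272-2516702)	bath-12,bath-13	+
chrII	13245000	13250000	5	-	-	-	-	F15D4.5,F15D4.6	+
chrIV	915000	922000	7	An extensive Cer3-1 (8.7 kb) with LTR in both ends	-	-	-	F58H7.5,F58H7.6	+
chrIV	4124000	4138000	14	A solo LTR (Cer2) with four other Cer2 fragments (275-412 bp)	-	-	-	F49F1.7,F49F1.8	+
chrIV	13633000	13639000	6	-	LINE2C1 fragment	-	-	C08F11.5,C08F11.7	+
chrV	5182000	5201000	19	Cer9-1 (11.5 kb) with LTR in both ends	-	-	-	C03A7.12,C03A7.2,C03A7.13,abu-8,Y47A7.2	+
chrV	5482000	5487000	5	-	-	-	-	srg-66,srg-65,grl-18	+
chrV	8826000	8837000	11	Mixed Cer8 and Cer9 sequence (19.8 kb) with LTR (Cer9) in both ends	-	-	-	F09B7.3,W09B7.2,W09B7.1,F07B7.7,F07B7.8	+
chrV	8868000	8879000	11	Mixed Cer8 and Cer9 sequence (19.8 kb) with LTR (Cer9) in both ends; identical sequence to chrV:8826000-8837000	-	-	-	F09B7.3,W09B7.2,W09B7.1,F07B7.7,F07B7.8	+
chrV	14039000	14055000	16	-	LINE2H	-	-	T08G5.9,T08G5.8,T08G5.7,F58D12.5,T08G5.19	-
chrV	17568000	17573000	5	A Cer8-1 fragment (68 bp)	-	-	-	C38D9.2	+
chrV	18439000	18457000	18	Cer8-1 (19.4 kb) with LTR in both ends	-	Tc1 embedded in the Cer8-1	-	ZK262.8,ZK262.9,ZK228.1,ZK228.10	+
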