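##gff-version 3
chr4	.	miRNA	112647873	112647894	.	-	.	ID=MIMAT0000000;Name=hsa-miR-367-3p
chr4	.	miRNA	112648063	112648085	.	-	.	ID=MIMAT0000001;Name=hsa-miR-302d-3p
chr4	.	miRNA	112648230	112648252	.	-	.	ID=MIMAT0000002;Name=hsa-miR-302a-3p
chr4	.	miRNA	112648405	112648427	.	-	.	ID=MIMAT0000003;Name=hsa-miR-302c-3p
chr4	.	miRNA	112648540	112648562	.	-	.	ID=MIMAT0000004;Name=hsa-miR-302b-3p
chr13	.	miRNA	92002876	92002898	.	+	.	ID=MIMAT0000005;Name=hsa-miR-17-5p
chr13	.	miRNA	92003005	92003027	.	+	.	ID=MIMAT0000006;Name=hsa-miR-18a-5p
chr13	.	miRNA	92003145	92003167	.	+	.	ID=MIMAT0000007;Name=hsa-miR-19a-3p
chr13	.	miRNA	92003319	92003341	.	+	.	ID=MIMAT0000008;Name=hsa-miR-20a-5p
chr13	.	miRNA	92003445	92003467	.	+	.	ID=MIMAT0000009;Name=hsa-miR-19b-3p
chr13	.	miRNA	92003568	92003589	.	+	.	ID=MIMAT0000010;Name=hsa-miR-92a-3p
chrX	.	miRNA	134169538	134169559	.	-	.	ID=MIMAT0000011;Name=hsa-miR-363-3p
chrX	.	miRNA	134169900	134169922	.	-	.	ID=MIMAT0000012;Name=hsa-miR-20b-5p
chrX	.	miRNA	134170200	134170222	.	-	.	ID=MIMAT0000013;Name=hsa-miR-18b-5p
chrX	.	miRNA	134170540	134170562	.	-	.	ID=MIMAT0000014;Name=hsa-miR-106a-5p
chr7	.	miRNA	100093560	100093581	.	-	.	ID=MIMAT0000015;Name=hsa-miR-25-3p
chr7	.	miRNA	100093768	100093790	.	-	.	ID=MIMAT0000016;Name=hsa-miR-93-5p
chr7	.	miRNA	100093993	100094013	.	-	.	ID=MIMAT0000017;Name=hsa-miR-106b-5p
chr1	.	miRNA	156420341	156420363	.	+	.	ID=MIMAT0000018;Name=hsa-miR-9-5p
chr8	.	miRNA	9903388	9903407	.	+	.	ID=MIMAT0000019;Name=hsa-miR-124-3p
chr9	.	miRNA	124692440	124692462	.	-	.	ID=MIMAT0000020;Name=hsa-miR-181a-5p
chr6	.	miRNA	71403551	71403572	.	-	.	ID=MIMAT0000021;Name=hsa-miR-30a-5p
chr9	.	miRNA	94175962	94175983	.	+	.	ID=MIMAT0000022;Name=hsa-let-7a-5p
chr12	.	miRNA	6963699	6963721	.	+	.	ID=MIMAT0000023;Name=hsa-miR-200c-3p
chr6	.	miRNA	33206580	33206600	.	+	.	ID=MIMAT0000024;Name=hsa-miR-219a-5p
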