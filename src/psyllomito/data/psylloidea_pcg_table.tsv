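species	gene	start_codon	stop_codon	length_bp
B_cockerelli	nad2	ATC	TAA	972
B_cockerelli	cox1	ATG	T	1531
B_cockerelli	cox2	ATT	T	664
B_cockerelli	atp8	ATC	TAA	153
B_cockerelli	atp6	ATG	TAA	675
B_cockerelli	cox3	ATG	TAA	783
B_cockerelli	nad3	ATT	TAA	351
B_cockerelli	nad5	ATT	T	1627
B_cockerelli	nad4	ATG	T	1243
B_cockerelli	nad4L	ATA	TAG	276
B_cockerelli	nad6	ATA	TAA	483
B_cockerelli	cob	ATA	TAG	1143
B_cockerelli	nad1	ATA	TAA	915
B_cockerelli	rrnL	.	.	1181
B_cockerelli	rrnS	.	.	800
P_sinica	nad2	ATT	T	970
P_sinica	cox1	ATA	TAA	1539
P_sinica	cox2	ATT	T	664
P_sinica	atp8	ATC	TAA	153
P_sinica	atp6	ATG	TA	674
P_sinica	cox3	ATG	TAA	783
P_sinica	nad3	ATT	T	349
P_sinica	nad5	TTG	T	1624
P_sinica	nad4	ATG	T	1240
P_sinica	nad4L	ATA	TAG	285
P_sinica	nad6	ATA	TAA	483
P_sinica	cob	ATA	T	1126
P_sinica	nad1	ATA	TAA	915
P_sinica	rrnL	.	.	1159
P_sinica	rrnS	.	.	802
C_coccinea	nad2	ATA	TAA	972
C_coccinea	cox1	ATG	TAA	1533
C_coccinea	cox2	ATA	T	664
C_coccinea	atp8	ATA	TAA	144
C_coccinea	atp6	ATG	TAA	675
C_coccinea	cox3	ATG	TAA	780
C_coccinea	nad3	ATA	T	352
C_coccinea	nad5	ATT	T	1621
C_coccinea	nad4	ATG	TAG	1287
C_coccinea	nad4L	ATA	TAG	261
C_coccinea	nad6	ATA	TAA	486
C_coccinea	cob	ATA	TAG	1146
C_coccinea	nad1	ATA	TAG	915
C_coccinea	rrnL	.	.	1154
C_coccinea	rrnS	.	.	773
P_venusta	nad2	ATG	TAA	978
P_venusta	cox1	ATG	T	1531
P_venusta	cox2	ATT	T	664
P_venusta	atp8	ATG	TAA	138
P_venusta	atp6	ATG	TAA	675
P_venusta	cox3	ATG	T	781
P_venusta	nad3	ATA	TAA	354
P_venusta	nad5	ATG	T	1618
P_venusta	nad4	ATG	T	1240
P_venusta	nad4L	ATA	TAG	273
P_venusta	nad6	ATA	TAA	480
P_venusta	cob	ATA	TAG	1137
P_venusta	nad1	ATT	TAA	915
P_venusta	rrnL	.	.	1148
P_venusta	rrnS	.	.	765
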