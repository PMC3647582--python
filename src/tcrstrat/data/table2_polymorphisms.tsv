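chain	region	position	substitution	genes	provenance
alpha	N-term	2	N/D	TRAV9-2	reference-catalog
alpha	CDR1	27	V/M	TRAV36;TRAV12-2;TRAV8-4;TRAV14-1;TRAV38-1;TRAV20	reference-catalog
alpha	CDR1	29	G/V	TRAV36;TRAV12-2;TRAV8-4;TRAV14-1;TRAV38-1;TRAV20	reference-catalog
alpha	CDR1	29	G/R	TRAV36;TRAV12-2;TRAV8-4;TRAV14-1;TRAV38-1;TRAV20	supplementary-literature
alpha	CDR1	30	N/S	TRAV36;TRAV12-2;TRAV8-4;TRAV14-1;TRAV38-1;TRAV20	supplementary-literature
alpha	CDR1	30	P/E	TRAV36;TRAV12-2;TRAV8-4;TRAV14-1;TRAV38-1;TRAV20	reference-catalog
alpha	CDR1	30	P/Q	TRAV36;TRAV12-2;TRAV8-4;TRAV14-1;TRAV38-1;TRAV20	reference-catalog
alpha	CDR1	31	N/D	TRAV36;TRAV12-2;TRAV8-4;TRAV14-1;TRAV38-1;TRAV20	reference-catalog
alpha	CDR1	32	Y/S	TRAV36;TRAV12-2;TRAV8-4;TRAV14-1;TRAV38-1;TRAV20	supplementary-literature
alpha	CDR2	55	F/S	TRAV12-2;TRAV1-1;TRAV8-4;TRAV14-1;TRAV25;TRAV8-7;TRAV26-2;TRAV38-1	reference-catalog
alpha	CDR2	56	Q/E	TRAV12-2;TRAV1-1;TRAV8-4;TRAV14-1;TRAV25;TRAV8-7;TRAV26-2;TRAV38-1	supplementary-literature
alpha	CDR2	57	A/G	TRAV12-2;TRAV1-1;TRAV8-4;TRAV14-1;TRAV25;TRAV8-7;TRAV26-2;TRAV38-1	reference-catalog
alpha	CDR2	57	V/M	TRAV12-2;TRAV1-1;TRAV8-4;TRAV14-1;TRAV25;TRAV8-7;TRAV26-2;TRAV38-1	supplementary-literature
alpha	CDR2	58	S/T	TRAV12-2;TRAV1-1;TRAV8-4;TRAV14-1;TRAV25;TRAV8-7;TRAV26-2;TRAV38-1	reference-catalog
alpha	CDR2	58	T/I	TRAV12-2;TRAV1-1;TRAV8-4;TRAV14-1;TRAV25;TRAV8-7;TRAV26-2;TRAV38-1	supplementary-literature
alpha	CDR2	59	A/G	TRAV12-2;TRAV1-1;TRAV8-4;TRAV14-1;TRAV25;TRAV8-7;TRAV26-2;TRAV38-1	reference-catalog
alpha	CDR2	59	K/E	TRAV12-2;TRAV1-1;TRAV8-4;TRAV14-1;TRAV25;TRAV8-7;TRAV26-2;TRAV38-1	supplementary-literature
alpha	CDR2	61	Q/E	TRAV12-2;TRAV1-1;TRAV8-4;TRAV14-1;TRAV25;TRAV8-7;TRAV26-2;TRAV38-1	reference-catalog
beta	CDR1	30	A/V	TRBV7-7;TRBV6-6	reference-catalog
beta	CDR1	30	N/E	TRBV7-7;TRBV6-6	reference-catalog
beta	CDR2	55	Q/H	TRBV9;TRBV19;TRBV30;TRBV15;TRBV20-1;TRBV10-1;TRBV3-1	reference-catalog
beta	CDR2	57	Q/H	TRBV9;TRBV19;TRBV30;TRBV15;TRBV20-1;TRBV10-1;TRBV3-1	reference-catalog
beta	CDR2	57	V/I	TRBV9;TRBV19;TRBV30;TRBV15;TRBV20-1;TRBV10-1;TRBV3-1	reference-catalog
beta	CDR2	58	D/N	TRBV9;TRBV19;TRBV30;TRBV15;TRBV20-1;TRBV10-1;TRBV3-1	reference-catalog
beta	CDR2	60	G/D	TRBV9;TRBV19;TRBV30;TRBV15;TRBV20-1;TRBV10-1;TRBV3-1	reference-catalog
beta	CDR2	60	S/C	TRBV9;TRBV19;TRBV30;TRBV15;TRBV20-1;TRBV10-1;TRBV3-1	reference-catalog
beta	CDR2	60	Q/H	TRBV9;TRBV19;TRBV30;TRBV15;TRBV20-1;TRBV10-1;TRBV3-1	reference-catalog
beta	CDR2	61	L/I	TRBV9;TRBV19;TRBV30;TRBV15;TRBV20-1;TRBV10-1;TRBV3-1	reference-catalog
beta	HV4	84	G/E	TRBV7-2	reference-catalog
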