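# Published log2 fold changes (treated vs control) for a rice cytokinin-response
# validation panel measured by RNA-Seq and NanoString nCounter in roots and shoots.
# "-" = not significant by RNA-Seq in that tissue; "nd" = no signal above the
# detection background in the treated sample; "ND" = no signal in either sample.
gene_id	description	root_rnaseq	root_nano	shoot_rnaseq	shoot_nano
Os02g51930	cytokinin-O-glucosyltransferase 2	2.51	1.31	-	-
Os07g13800	cytokinin-N-glucosyltransferase	1.82	1.74	-	-
Os11g12300	NBS-LRR disease resistance protein	2.39	2.01	-	-
Os11g12320	disease resistance protein RPM1	2.14	1.86	-	-
Os03g55080	WRKY3	1.07	0.71	-	-
Os05g46020	WRKY7	3.829	2.73	-	-
Os05g25770	WRKY45	3.24	1.95	-	-
Os09g25070	WRKY62	4.23	2.42	-	-
Os05g09020	WRKY67	3.15	2.50	-	-
Os07g48630	ethylene-insensitive 3	1.09	1.14	-	-
Os02g03410	CAMK_like.12	2.09	2.12	-	-
Os02g53180	1-aminocyclopropane-1-carboxylate oxidase	4.01	3.12	-	-
Os03g29410	tyrosine protein kinase domain containing protein	2.14	1.80	-	-
Os03g42070	Cyclin	-1.94	nd	-	-
Os03g46440	BTBA4 - Bric-a-Brac	2.18	1.56	-	-
Os06g39590	OsIAA23	1.70	1.37	-	-
Os07g11739	cytochrome P450	4.20	1.71	-	-
Os07g40630	BRASSINOSTEROID INSENSITIVE 1 precursor	1.75	1.57	-	-
Os09g38210	auxin efflux carrier component	2.35	1.59	-	-
Os02g13900	BES1/BZR1 homolog protein	-	-	1.01	0.80
Os04g57720	OsRR6	4.89	3.77	3.95	1.21
Os12g43110	OsSAUR58	-1.41	-2.39	-	-
Os10g20260	CSLF7 - cellulose synthase-like family F	-4.29	-3.10	-	-
Os04g44670	AP2 domain containing protein	-2.04	-1.60	-	-
Os04g39980	gibberellin 20 oxidase 2	-1.66	-1.06	-	-
Os04g52670	OsSAUR21	1.02	0.49	0.72	0.68
Os07g48830	glycosyl transferase 8 domain containing protein	3.13	1.14	-0.85	-0.63
Os11g05470	RCN1 Centroradialis-like1 homologous to TFL1	-2.53	-2.75	2.07	0.53
Os01g09640	Myb transcription factor	1.24	0.20	-0.58	-0.56
Os08g42080	ACR5	-0.95	-0.85	3.24	1.85
Os01g55240	gibberellin 2-beta-dioxygenase	-1.04	-0.11	0.97	-0.08
Os07g06860	gibberellin receptor GID1L2	-1.61	-1.62	2.67	ND
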