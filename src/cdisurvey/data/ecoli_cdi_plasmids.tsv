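accession	n_cdi_systems	plasmid_size	strain
CP027343.1	1	131410	2014C-4587
CP010214.1	1	146496	M15
CP027453.1	1	159611	2014C-3338
CP009107.1	1	161447	94-3024
CP023542.1	1	161452	CFSAN002236
CP011019.1	1	207265	CI5
CP010181.1	1	201930	M1
CP010207.1	1	138950	M11
CP010184.1	1	200925	M3
CP023164.1	1	122641	RM10809-3
CP010192.1	1	162720	M8
CP061330.1	2	127456	EC93
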