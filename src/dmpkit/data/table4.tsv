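habitat	population	n_sampled	n_haploid	n_diploid	mean_n_alleles	se_n_alleles	allelic_richness	private_alleles
mainland	Nice11	190	172	10	6.78	0.92	3.37	8
mainland	Nice13	90	85	2	6.00	0.75	3.52	0
mainland	Sol13	16	12	1	3.78	0.43	3.58	2
mainland	VS13	58	49	3	5.67	0.78	3.41	3
mainland	Vy13	33	30	1	5.22	0.64	3.68	4
island	Mlc12	21	18	3	4.22	0.43	3.27	0
island	Mlc13	38	33	4	4.56	0.47	3.25	1
captive	CapNiceA	50	43	7	4.33	0.37	3.32	0
captive	CapNiceB	31	26	1	3.78	0.52	3.04	0
captive	CapVal	50	48	1	3.67	0.44	3.08	0
captive	CapIsr	50	42	8	2.44	0.24	2.05	0
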