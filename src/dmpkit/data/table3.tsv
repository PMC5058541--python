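multiplex	locus	n_alleles	nice10_he	nice10_ho	nice10_hw_p	nice10_null	val10_he	val10_ho	val10_hw_p	val10_null
I	VC068	7	0.742	0.727	0.848	0.012	0.826	0.865	0.771	0.000
I	Vcan071	11	0.809	0.750	0.493	0.036	0.798	0.838	0.728	0.000
I	VC092	7	0.636	0.705	0.390	0.000	0.600	0.676	1.000	0.000
I	VC094	4	0.592	0.545	0.771	0.034	0.511	0.541	0.813	0.000
I	VC009	8	0.697	0.864	0.135	0.000	0.649	0.703	1.000	0.000
I	VC036	7	0.540	0.568	0.771	0.000	0.450	0.432	0.771	0.000
I	VC002	7	0.577	0.591	0.813	0.026	0.716	0.757	0.771	0.000
I	VC001	12	0.600	0.477	0.370	0.090	0.655	0.595	0.176	0.046
I	VC066	2	0.487	0.386	0.509	0.069	0.491	0.486	1.000	0.003
I	VC060	8	0.549	0.591	0.927	0.000	0.558	0.568	0.135	0.011
II	VC106	4	0.711	0.750	0.976	0.000	0.728	0.676	0.307	0.019
II	Vcan073	10	0.672	0.818	0.746	0.000	0.706	0.541	0.135	0.092
II	VC047	5	0.573	0.636	0.821	0.000	0.607	0.541	0.396	0.013
II	VC031	14	0.650	0.591	0.390	0.048	0.674	0.595	0.493	0.083
II	VC006	11	0.673	0.773	0.813	0.000	0.593	0.595	0.771	0.000
II	VC120	7	0.515	0.500	0.771	0.000	0.593	0.459	0.135	0.059
II	Vcan106	14	0.875	0.886	0.400	0.008	0.836	0.919	0.746	0.000
II	VC107	6	0.724	0.705	0.493	0.000	0.603	0.622	0.479	0.022
II	Vcan088	7	0.644	0.682	0.813	0.009	0.489	0.541	0.821	0.000
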