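feature_id	log2fc	p_value	regulation	gc_percent	circ_type
circRNA03556	22.53377519	0.013892798	Up	45.40229885	Exonic
circRNA03725	21.92096778	0.001434715	Up	40.90909091	Exonic
circRNA01979	21.48389791	0.000544358	Up	47.88069074	Exonic
circRNA00533	20.45822601	0.025267743	Up	43.75	Exonic
circRNA01891	19.93244316	0.012664519	Up	44.94382022	Exonic
circRNA03723	18.71480295	0.000533453	Up	39.52113509	Exonic
circRNA04809	18.26752047	0.040125467	Up	60.10781671	Exonic
circRNA00343	3.559259969	0.013435605	Up	44.24951267	Exonic
circRNA03712	2.066163958	0.000549785	Up	41.26106195	Exonic
circRNA01543	1.931690653	0.013484152	Up	68.37606838	Exonic
circRNA03390	1.881637631	0.018354902	Up	52.32903865	Exonic
circRNA03847	1.734807686	0.022120789	Up	45.40441176	Exonic
circRNA00982	1.695434754	0.001141365	Up	34.39878234	Exonic
circRNA02067	1.469244466	0.018185027	Up	51.09649123	Exonic
circRNA01985	1.402530297	0.003080891	Up	51.76056338	Exonic
circRNA00825	1.140773707	0.001808919	Up	44.38239893	Exonic
circRNA03309	1.030662355	0.025049036	Up	52.29681979	Exonic
circRNA02418	-1.033076974	0.017550638	Down	42.22440945	Exonic
circRNA04488	-1.133775465	0.009987767	Down	49.91776316	Exonic
circRNA01605	-1.177668696	0.045440296	Down	55.20446097	Exonic
circRNA03073	-1.325214463	0.023002072	Down	41.03819785	Exonic
circRNA02313	-1.512189587	0.016491331	Down	48.03293687	Exonic
circRNA00723	-1.734546089	0.000427638	Down	46.40522876	Exonic
circRNA00447	-1.803989196	0.015843509	Down	41.18476728	Exonic
circRNA03673	-1.817298272	0.001569667	Down	50.70063694	Exonic
circRNA04655	-2.051676194	0.025000319	Down	46.46924829	Exonic
circRNA00747	-2.153043019	0.0251707	Down	38.07649044	Exonic
circRNA03674	-2.508877673	0.004209075	Down	49.73758579	Exonic
circRNA03831	-3.183369042	0.013633279	Down	41.19496855	Exonic
circRNA06452	-19.42529847	0.015893812	Down	46.24277457	Exonic
circRNA08673	-19.74008741	0.006766295	Down	50.51282051	Exonic
circRNA06661	-19.98418488	0.047256341	Down	38.2183908	Exonic
circRNA08440	-20.39221528	0.010326992	Down	52.07995678	Exonic
circRNA09919	-22.18106979	0.034379652	Down	46.51685393	Exonic
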