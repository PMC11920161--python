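dataset	om_average	om_concat	om_hadamard	mlp_cd_average	mlp_cd_concat	mlp_cd_hadamard	cd2_average	cd2_concat	cd2_hadamard
HOC1	4.2	5.8	4.4	18.0	14.6	25.2	50.4	26.2	1.4
HOC2	101	106.4	121.8	205.2	170.4	210.6	5.8	7.4	13.4
HOC3	24.8	56.6	28.2	14.4	16.4	23.0	76.6	123.2	254.2
HOC4	112.6	68	117.4	300.0	234.4	323.4	256.2	115.8	21.0
HOC5	254.4	205.2	171.4	179.6	166.8	247.8	67.2	84.4	597.4
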