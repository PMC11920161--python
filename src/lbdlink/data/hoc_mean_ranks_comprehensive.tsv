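dataset	om_average	om_concat	om_hadamard	mlp_cd_average	mlp_cd_concat	mlp_cd_hadamard
HOC1	4.6	6.2	4.4	19.0	17.6	27.2
HOC2	147	146.6	185.6	350	275.8	384.4
HOC3	34	99.8	35.8	35.4	37.2	53.2
HOC4	289.4	132.6	301	300	234.4	323.4
HOC5	410.8	329.8	309.2	239.2	209.8	417.2
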