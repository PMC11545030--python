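name	sequence	start	end
E1	LIVTQTMKGLDIQKV	1	15
E2	KPTPEGDLEILLQK	47	60
E3	LQKWENDECAQKKIIAEKTK	58	77
E4	IAEKTKIPAVFKIDA	72	86
E5	EVDDEALEKFDKALKALP	127	144
E6	KALKALPMHIRLSFN	138	152
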