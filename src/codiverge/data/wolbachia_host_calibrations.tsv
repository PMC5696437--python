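source	host_a	host_b	host_ks	host_ka	symb_ks	symb_ka	ratio	cladogenic
This work	Drosophila suzukii	Drosophila subpulchrella	1.2e-1	6.8e-3	3e-5	4e-5	0.00025	0
Raychoudhury et al. 2009	Nasonia giraulti	Nasonia longicornis	1.22e-2	5.4e-3	3.7e-3	2.2e-3	0.30	1
Gerth & Bleidorn 2016	Nomada ferruginata	Nomada leucophthalma	1.95e-2	2.6e-3	2.5e-3	9e-4	0.13	1
Gerth & Bleidorn 2016	Nomada ferruginata	Nomada flava	1.92e-2	2.7e-3	2.5e-3	9e-4	0.13	1
Gerth & Bleidorn 2016	Nomada ferruginata	Nomada panzeri	1.84e-2	3.1e-3	2.7e-3	1.1e-3	0.15	1
Gerth & Bleidorn 2016	Nomada leucophthalma	Nomada flava	6.8e-3	4e-4	1e-4	1e-4	0.015	1
Gerth & Bleidorn 2016	Nomada leucophthalma	Nomada panzeri	5.8e-3	8e-4	3e-4	2e-4	0.052	1
Gerth & Bleidorn 2016	Nomada flava	Nomada panzeri	5.5e-3	9e-4	3e-4	3e-4	0.055	1
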