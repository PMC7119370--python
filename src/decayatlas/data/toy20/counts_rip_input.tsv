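gene_id	rip_input
g01	1000
g02	1000
g03	200
g04	2000
g05	10000
g06	300
g07	150
g08	100
g09	400
g10	500
g11	800
g12	50
g13	50
g14	0
g15	0
g16	900
g17	1000
g18	4000
g19	100
g20	6000
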