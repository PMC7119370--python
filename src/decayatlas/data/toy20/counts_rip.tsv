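gene_id	rip_pulldown
g01	3000
g02	1000
g03	100
g04	2000
g05	5000
g06	600
g07	150
g08	400
g09	200
g10	1000
g11	400
g12	50
g13	500
g14	200
g15	0
g16	1350
g17	1600
g18	2000
g19	100
g20	3000
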