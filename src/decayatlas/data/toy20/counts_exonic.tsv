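gene_id	liver_exon
g01	1000
g02	1
g03	0
g04	3
g05	2
g06	500
g07	200
g08	300
g09	400
g10	400
g11	600
g12	250
g13	250
g14	250
g15	250
g16	800
g17	800
g18	4000
g19	100
g20	5000
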