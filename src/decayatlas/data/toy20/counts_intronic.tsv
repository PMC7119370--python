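gene_id	liver_intron
g01	1000
g02	100
g03	50
g04	40
g05	100
g06	5
g07	1
g08	0
g09	5
g10	10
g11	9
g12	50
g13	60
g14	70
g15	80
g16	20
g17	25
g18	100
g19	40
g20	600
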