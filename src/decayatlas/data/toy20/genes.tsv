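gene_id	exon_length_bp	intron_length_bp
g01	1000	1000
g02	10000	1000
g03	1000	1000
g04	20000	2000
g05	100000	5000
g06	1000	10
g07	1000	29
g08	1000	0
g09	1000	1000
g10	1000	1000
g11	2000	1000
g12	1000	1000
g13	1000	1000
g14	1000	1000
g15	1000	1000
g16	1000	500
g17	1000	500
g18	4000	2000
g19	1000	1000
g20	1000	1000
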