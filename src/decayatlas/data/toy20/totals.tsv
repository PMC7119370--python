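sample_id	region	library_total
liver_exon	exonic	1000000000
liver_intron	intronic	1000000000
rip_input	exonic	1000000000
rip_pulldown	exonic	1000000000
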