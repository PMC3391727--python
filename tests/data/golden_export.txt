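# application=0.1.0 data=toy-1.0 modified=2012-04-30
# taxa_remaining=2
TAXON	Alpha Smith, 1900
TAXON	Gamma Brown, 1920
STATE	HEAD	eye pubescence	bare
STATE	WING	costal spine	absent; short
FILTER	length_mm=7
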