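# Illustrative IUPAC motif library for promoter-module scanning.
# These consensi are textbook approximations (C/EBP family site, TATA box,
# CAAT box) supplied ONLY as a worked example of the motif file format; they
# are not a curated venom-gland regulatory module.
CEBP_site	TTGCGCAA
CEBP_half	TKNNGNAA
TATA_box	TATAWAWR
CAAT_box	GGYCAATCT
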