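# Plant cis-regulatory element dictionary: one documented consensus variant per
# element name. Databases host several variants per element; these patterns are
# editable data (IUPAC DNA), not code.
name	pattern	category
G-box	CACGTG	light
GATA-motif	GATAGGG	light
Box 4	ATTAAT	light
GT1-motif	GGTTAA	light
TGA-element	AACGAC	hormone
P-box	CCTTTTG	hormone
TCA-element	CCATCTTTTT	hormone
CGTCA-motif	CGTCA	hormone
ABRE	ACGTG	hormone
LTR	CCGAAA	stress
GC-motif	CCCCCG	stress
MBS	CAACTG	stress
TC-rich repeats	GTTTTCTTAC	stress
CAT-box	GCCACT	development
MBSI	AAAAAACGGTTA	development
circadian	CAANNNNATC	development
HD-Zip 1	CAATWATTG	development
o2-site	GATGAYRTGR	development
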