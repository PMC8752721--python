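# Default regulator list bundled with keyreg (synthetic stand-in).
# A hand-curated set of widely studied human transcription factors and
# co-factors, provided so the pipeline runs out of the box on human gene
# symbols.  It is NOT a comprehensive TF census: for real analyses supply
# your own regulator list (one ID per line) via --regulators / config.
AHR
AR
ARNT
ATF1
ATF2
ATF3
ATF4
ATF6
BACH1
BACH2
BATF
BCL6
CEBPA
CEBPB
CEBPD
CIITA
CLOCK
CREB1
CREBBP
CTCF
E2F1
E2F2
E2F3
E2F4
EGR1
EGR2
EGR3
ELF1
ELF4
ELK1
ELK4
EOMES
EP300
ERG
ESR1
ESR2
ETS1
ETS2
ETV4
ETV6
ETV7
FLI1
FOS
FOSB
FOSL1
FOSL2
FOXA1
FOXA2
FOXM1
FOXO1
FOXO3
FOXP1
FOXP3
GATA1
GATA2
GATA3
GATA4
GATA6
GFI1
GLI1
GLI2
HAND1
HES1
HEY1
HIF1A
HMGA1
HNF1A
HNF4A
HOXA9
HSF1
ID2
IKZF1
IRF1
IRF2
IRF3
IRF4
IRF5
IRF6
IRF7
IRF8
IRF9
JUN
JUNB
JUND
KLF2
KLF4
KLF5
KLF6
LEF1
MAF
MAFB
MAX
MEF2A
MEF2C
MITF
MYB
MYBL2
MYC
MYCN
MYOD1
NANOG
NCOA1
NCOA3
NFATC1
NFATC2
NFE2L2
NFIL3
NFKB1
NFKB2
NFYA
NKX2-1
NOTCH1
NR1H3
NR3C1
NR4A1
PAX5
PAX6
PPARA
PPARD
PPARG
PRDM1
RARA
RB1
REL
RELA
RELB
RFX5
RORA
RORC
RUNX1
RUNX2
RUNX3
RXRA
SMAD2
SMAD3
SMAD4
SNAI1
SNAI2
SOX2
SOX9
SP1
SP3
SPI1
SREBF1
SREBF2
SRF
STAT1
STAT2
STAT3
STAT4
STAT5A
STAT5B
STAT6
T
TAL1
TBX21
TCF3
TCF4
TCF7
TEAD1
TFAP2A
TFAP2C
TFEB
TP53
TP63
TP73
TWIST1
USF1
USF2
VDR
WT1
XBP1
YY1
ZEB1
ZEB2
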