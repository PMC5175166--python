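# 52-TF Ensembl GRCh38.p3 catalogue (names only; build target sets from GFF3+BED)
RXRA	Ensembl_GRCh38.p3	
SRF	Ensembl_GRCh38.p3	
SPI1	Ensembl_GRCh38.p3	
YY1	Ensembl_GRCh38.p3	
PAX5	Ensembl_GRCh38.p3	
JUND	Ensembl_GRCh38.p3	
CTCF	Ensembl_GRCh38.p3	
CTCFL	Ensembl_GRCh38.p3	
E2F4	Ensembl_GRCh38.p3	
E2F6	Ensembl_GRCh38.p3	
MEF2A	Ensembl_GRCh38.p3	
ELF1	Ensembl_GRCh38.p3	
EGR1	Ensembl_GRCh38.p3	
SP1	Ensembl_GRCh38.p3	
POU2F2	Ensembl_GRCh38.p3	
ZNF263	Ensembl_GRCh38.p3	
USF1	Ensembl_GRCh38.p3	
SP2	Ensembl_GRCh38.p3	
ETS1	Ensembl_GRCh38.p3	
EBF1	Ensembl_GRCh38.p3	
THAP1	Ensembl_GRCh38.p3	
MYC	Ensembl_GRCh38.p3	
MYC::MAX	Ensembl_GRCh38.p3	
HNF4A	Ensembl_GRCh38.p3	
NR1H3::RXRA	Ensembl_GRCh38.p3	
MAX	Ensembl_GRCh38.p3	
NRF1	Ensembl_GRCh38.p3	
RXRA::VDR	Ensembl_GRCh38.p3	
JUN	Ensembl_GRCh38.p3	
REST	Ensembl_GRCh38.p3	
FOSL2	Ensembl_GRCh38.p3	
JUN::FOS	Ensembl_GRCh38.p3	
ZEB1	Ensembl_GRCh38.p3	
ZBTB33	Ensembl_GRCh38.p3	
GATA2	Ensembl_GRCh38.p3	
GATA1	Ensembl_GRCh38.p3	
BHLHE40	Ensembl_GRCh38.p3	
FOXA1	Ensembl_GRCh38.p3	
JUNB	Ensembl_GRCh38.p3	
FOS	Ensembl_GRCh38.p3	
FOSL1	Ensembl_GRCh38.p3	
NR2C2	Ensembl_GRCh38.p3	
TCF12	Ensembl_GRCh38.p3	
MEF2C	Ensembl_GRCh38.p3	
HNF4G	Ensembl_GRCh38.p3	
PPARG::RXRA	Ensembl_GRCh38.p3	
RXR::RAR_DR5	Ensembl_GRCh38.p3	
TAL1::GATA1	Ensembl_GRCh38.p3	
PBX3	Ensembl_GRCh38.p3	
ECR::USP	Ensembl_GRCh38.p3	
IRF4	Ensembl_GRCh38.p3	
FOXA2	Ensembl_GRCh38.p3	
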