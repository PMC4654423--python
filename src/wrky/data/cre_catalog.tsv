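name	iupac	description
WBOXNT	YTGACY	W-box, core binding site of WRKY transcription factors
WRKY71OS	TGAC	Minimal WRKY-binding W-box core
CAATBOX1	CAAT	CAAT enhancer-region element
GATABOX	GATA	Light-responsive GATA element
DOFCOREZM	AAAG	Core binding site of Dof proteins
EBOXBNNAPA	CANNTG	E-box, bHLH/MYB target site
MYCCONSENSUSAT	CANNTG	MYC recognition site
ARR1AT	NGATT	Cytokinin-responsive ARR1 binding element
CACTFTPPCA1	YACT	Mesophyll-specific expression element of C4 PEPC
ABRELATERD1	ACGTG	ABA-responsive element core
HSE	AGAANNTTCT	Heat-shock element consensus
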