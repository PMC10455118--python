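# Curated mapping of plant-biomass-degradation CAZy (sub-)families to enzyme
# activities and the plant polysaccharide each activity attacks.
# Subfamily-resolved rows (e.g. GH5_7) are distinct catalog units; bare-family
# queries roll subfamilies up.
family	activity_code	substrate	provenance
GH12	EGL	cellulose	endoglucanase acting on amorphous cellulose
GH131	EGL	cellulose	endoglucanase acting on amorphous cellulose
GH45	EGL	cellulose	endoglucanase acting on amorphous cellulose
GH5_4	EGL	cellulose	endoglucanase subfamily of GH5
GH5_5	EGL	cellulose	endoglucanase subfamily of GH5
GH5_22	EGL	cellulose	endoglucanase subfamily of GH5
GH7	CBH	cellulose	cellobiohydrolase I, reducing chain ends
GH6	CBH	cellulose	cellobiohydrolase II, non-reducing chain ends
GH1	BGL	cellulose	beta-glucosidase cleaving cellobiose to glucose
GH3	BGL	cellulose	beta-glucosidase cleaving cellobiose to glucose
AA9	LPMO	cellulose	lytic polysaccharide monooxygenase, oxidative cellulose cleavage
AA16	LPMO	cellulose	lytic polysaccharide monooxygenase, boosts cellulase activity
AA3_1	CDH	cellulose	cellobiose dehydrogenase supporting oxidative cellulose attack
GH10	XLN	xylan	beta-D-endoxylanase
GH11	XLN	xylan	beta-D-endoxylanase
GH30_7	XBH	xylan	beta-xylobiohydrolase
GH3	BXL	xylan	beta-xylosidase releasing xylose from xylo-oligosaccharides
GH43	BXL	xylan	beta-xylosidase releasing xylose from xylo-oligosaccharides
GH43	ABF	xylan	alpha-L-arabinofuranosidase removing arabinose decorations
GH51	ABF	xylan	alpha-L-arabinofuranosidase removing arabinose decorations
GH54	ABF	xylan	alpha-L-arabinofuranosidase removing arabinose decorations
GH62	AXH	xylan	arabinoxylan arabinofuranohydrolase
GH67	AGU	xylan	alpha-glucuronidase removing glucuronic acid side groups
GH115	AGU	xylan	alpha-glucuronidase removing glucuronic acid side groups
CE15	GE	xylan	glucuronoyl esterase, lignin-glucuronoxylan ester linkages
CE1	AXE	xylan	acetyl xylan esterase
CE5	AXE	xylan	acetyl xylan esterase
CE16	HAE	xylan	hemicellulose acetyl esterase
FAE	FAE	xylan	feruloyl esterase releasing ferulate from arabinoxylan
GH29	AFC	xyloglucan	alpha-fucosidase removing fucose decorations
GH95	AFC	xyloglucan	alpha-fucosidase removing fucose decorations
GH141	AFC	xyloglucan	alpha-fucosidase with open active-site pocket
GH12	XEG	xyloglucan	xyloglucan beta-1,4-endoglucanase
GH44	XEG	xyloglucan	xyloglucan beta-1,4-endoglucanase
GH74	XEG	xyloglucan	xyloglucan beta-1,4-endoglucanase
GH31	AXL	xyloglucan	alpha-xylosidase removing xylose side groups
GH2	LAC	xyloglucan	beta-1,4-galactosidase removing galactose decorations
GH35	LAC	xyloglucan	beta-1,4-galactosidase removing galactose decorations
GH43	ABF	xyloglucan	alpha-L-arabinofuranosidase, arabinose decorations on xyloglucan
GH51	ABF	xyloglucan	alpha-L-arabinofuranosidase, arabinose decorations on xyloglucan
GH54	ABF	xyloglucan	alpha-L-arabinofuranosidase, arabinose decorations on xyloglucan
CE16	HAE	xyloglucan	hemicellulose acetyl esterase, acetylated xyloglucan
GH5_7	MAN	mannan	beta-1,4-endomannanase subfamily of GH5
GH26	MAN	mannan	beta-1,4-endomannanase
GH134	MAN	mannan	beta-1,4-endomannanase
GH2	MND	mannan	beta-1,4-mannosidase
GH27	AGL	mannan	alpha-galactosidase on galactomannan
GH36	AGL	mannan	alpha-galactosidase on galactomannan
CE16	HAE	mannan	hemicellulose acetyl esterase, acetylated mannan
GH2	PH	pectin	pectin hydrolase, rhamnogalacturonan side chains
GH5_16	PH	pectin	pectin hydrolase subfamily of GH5
GH28	PH	pectin	polygalacturonase-type pectin hydrolase
GH35	PH	pectin	pectin hydrolase, galactan side chains
GH43	PH	pectin	pectin hydrolase, arabinan side chains
GH51	PH	pectin	pectin hydrolase, arabinan side chains
GH53	GAL	pectin	endo-beta-1,4-galactanase on pectic galactan
GH54	PH	pectin	pectin hydrolase, arabinan side chains
GH78	PH	pectin	alpha-rhamnosidase-type pectin hydrolase
GH88	PH	pectin	unsaturated glucuronyl hydrolase-type pectin hydrolase
GH93	PH	pectin	exo-arabinanase-type pectin hydrolase
GH105	PH	pectin	unsaturated rhamnogalacturonyl hydrolase
PL1	PLY	pectin	pectin/pectate lyase
PL3	PLY	pectin	pectate lyase
PL4	PLY	pectin	rhamnogalacturonan lyase
PL9	PLY	pectin	pectate lyase
PL11	PLY	pectin	rhamnogalacturonan lyase
CE8	PME	pectin	pectin methylesterase
CE12	RGAE	pectin	pectin/rhamnogalacturonan acetyl esterase
FAE	FAE	pectin	feruloyl esterase releasing ferulate esterified to pectin side chains
GH13_40	AGD	starch	alpha-glucosidase
GH31	AGD	starch	alpha-glucosidase
GH133	AMG	starch	amylo-alpha-1,6-glucosidase debranching amylopectin
GH13_1	AMY	starch	alpha-amylase
GH13_5	AMY	starch	alpha-amylase
GH15	GLA	starch	glucoamylase
AA13	LPMO	starch	starch-active lytic polysaccharide monooxygenase
GH32	INU	inulin	endo-/exo-inulinase and invertase; sole inulinolytic family
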