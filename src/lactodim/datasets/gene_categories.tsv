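symbol	fold_change	p_value	description	chromosome	angiogenesis	cell_growth_proliferation	cell_death_survival	cell_morphology	cellular_movement	development	endocrine_system	estrogen_signaling	pituitary_tumors	sexual_dimorphism
BHLHE41	2.077	0.00365	Basic helix-loop-helix family member e41	12	0	0	0	0	1	1	0	1	0	0
CDK8	2.599	5.59e-5	Cyclin dependent kinase 8	13	0	1	0	0	0	0	0	1	0	0
CHL1	3.117	0.0296	Cell adhesion molecule L1 like	3	0	1	0	1	1	1	0	0	1	0
CTAG2	2.332	0.0242	Cancer/testis antigen 2	X	0	0	0	0	1	0	0	1	0	0
ENC1	2.023	0.0336	Ectodermal-neural cortex 1	5	0	1	0	1	1	0	0	0	1	0
ERBIN	2.008	0.0191	Erbb2 interacting protein	5	0	1	0	1	0	1	0	1	0	1
ETS2	2.366	5.76e-4	ETS proto-oncogene 2, transcription factor	21	0	0	1	0	0	1	0	1	1	0
EXT1	2.181	0.00196	Exostosin glycosyltransferase 1	8	0	1	0	0	1	1	0	1	0	0
EZR	-2.199	0.0187	Ezrin	6	0	1	0	1	1	1	0	0	1	0
FGF13	3.419	0.0067	Fibroblast growth factor 13	X	0	1	1	1	1	1	0	1	0	0
FOXA1	2.35	0.0338	Forkhead box A1	14	0	1	0	1	1	1	1	1	0	1
FOXQ1	5.758	0.0393	Forkhead box Q1	6	0	0	0	0	1	1	0	1	0	0
GADD45G	-2.656	0.0281	Growth arrest and DNA damage inducible gamma	9	0	1	0	0	0	0	0	0	1	0
ISL1	2.163	0.0338	ISL LIM homeobox 1	5	1	1	1	0	1	1	1	0	0	0
KDM5D	18.032	4.12e-10	Lysine demethylase 5d	Y	0	1	0	0	0	0	0	0	0	1
LTBP1	2.246	0.0367	Latent transforming growth factor beta binding protein 1	2	1	1	1	0	0	1	0	1	1	1
MYH7	-4.706	0.00688	Myosin heavy chain 7	14	0	0	0	0	0	1	0	1	0	0
NMU	3.336	0.00721	Neuromedin u	4	0	0	0	0	1	0	0	1	0	0
OBSCN	2.596	0.0158	Obscurin, cytoskeletal calmodulin and titin-interacting rhogef	1	0	0	1	0	0	0	0	1	0	0
PITX1	2.459	0.00579	Paired like homeodomain 1	5	0	0	0	0	0	1	1	1	1	0
PPID	2.261	0.0369	Peptidylprolyl isomerase d	4	0	0	0	0	1	0	0	0	0	1
PTGS1	2.554	0.0263	Prostaglandin-endoperoxide synthase 1	9	1	0	0	0	0	1	1	1	0	0
PTPRZ1	2.393	0.0496	Protein tyrosine phosphatase, receptor type z1	7	1	1	0	1	1	1	0	1	0	0
ROBO1	2.033	0.0144	Roundabout guidance receptor 1	3	1	1	0	1	1	1	0	1	0	0
SLC12A4	3.348	0.00534	Solute carrier family 12 member 4	16	0	0	0	0	0	1	0	0	1	0
SLC2A11	2.342	0.0131	Solute carrier family 2 member 11	22	0	1	0	0	0	0	1	0	1	0
SLC6A8	2.577	0.00231	Solute carrier family 6 member 8	X	0	0	1	0	0	0	0	1	0	1
SNCB	2.022	0.013	Synuclein beta	5	0	0	0	1	0	1	0	1	0	0
SOSTDC1	6.814	0.0103	Sclerostin domain containing 1	7	0	0	0	0	0	1	0	1	0	0
STAP2	2.122	0.00363	Signal transducing adaptor family member 2	19	0	0	0	0	1	0	0	1	0	0
TSPAN8	3.232	0.0371	Tetraspanin 8	12	0	0	0	0	1	0	0	1	0	0
VEGFD	2.27	0.0363	vascular endothelial growth factor d	X	1	1	0	1	1	1	0	0	1	0
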