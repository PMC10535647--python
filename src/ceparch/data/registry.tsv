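name	accession_db	accession	species	strain	model_id
PrtB	uniprot	Q48545	Lactobacillus delbrueckii subsp. bulgaricus	NCDO1489	ma-uvrke
PrtH	uniprot	Q9S4K2	Lactobacillus helveticus	CNRZ32	ma-8ai4c
PrtH2	uniprot	A4UAD8	Lactobacillus helveticus	CNRZ32	ma-pes1m
PrtH3_CNRZ32	uniprot	G8DA68	Lactobacillus helveticus	CNRZ32
PrtH3_DSM20075	genbank	EEW67121.1	Lactobacillus helveticus	DSM 20075
PrtH4	uniprot	G8DA69	Lactobacillus helveticus	CNRZ32
PrtL	genbank	EPB98635.1	Lactobacillus delbrueckii subsp. lactis	CRL581	ma-sthfc
PrtS_4F44	uniprot	D3KCP7	Streptococcus thermophilus	4F44	ma-8wf3g
PrtS_LMD-9	genbank	WP_011681052.1	Streptococcus thermophilus	LMD-9
PrtP_MS22333	genbank	WWDI00000000	Lactococcus lactis	MS22333	ma-iisw7
PrtP_MS22337	genbank	WWDK00000000	Lactococcus lactis	MS22337	ma-1x50w
PrtP_NCDO151	uniprot	Q02470	Lacticaseibacillus paracasei subsp. paracasei	NCDO151
PrtP_SK11	genbank	DQ149245.1	Lactococcus lactis subsp. cremoris	SK11	ma-bevya
PrtP_Wg2	uniprot	P16271	Lactococcus lactis subsp. cremoris	Wg2	ma-r3cva
PrtR	uniprot	Q8GC13	Lacticaseibacillus rhamnosus	BGT10	ma-i7gkn
ScpA	uniprot	P15926	Streptococcus pyogenes	B220	3EIF
ScpC	uniprot	Q3HV58	Streptococcus pyogenes		5XYR
Subtilisin	uniprot	P00780	Bacillus licheniformis		AF-P00780
PrtP_NFICC1	genbank	OQ263285	Enterococcus durans	NFICC1
PrtP_NFICC14	genbank	OQ263286	Enterococcus durans	NFICC14
PrtP_NFICC16	genbank	OQ263287	Enterococcus durans	NFICC16
PrtP_NFICC18	genbank	OQ263288	Enterococcus durans	NFICC18
PrtP_NFICC63	genbank	OQ263289	Enterococcus durans	NFICC63
PrtP_NFICC64	genbank	OQ263290	Enterococcus durans	NFICC64
PrtP_NFICC80	genbank	OQ263291	Leuconostoc lactis	NFICC80	ma-8yfr1
PrtP_NFICC96H	genbank	OQ263292	Leuconostoc pseudomesenteroides	NFICC96	ma-b49jj
PrtP_NFICC96Q	genbank	OQ263293	Leuconostoc pseudomesenteroides	NFICC96	ma-eoqml
PrtP_NFICC96W	genbank	OQ263294	Leuconostoc pseudomesenteroides	NFICC96	ma-5kpc0
PrtP_NFICC99	genbank	OQ263295	Leuconostoc pseudomesenteroides	NFICC99
PrtP_NFICC102	genbank	OQ263296	Leuconostoc pseudomesenteroides	NFICC102
PrtP_NFICC103	genbank	OQ263297	Pediococcus pentosaceus	NFICC103	ma-u453p
PrtP_NFICC115	genbank	OQ263298	Leuconostoc mesenteroides	NFICC115
PrtP_NFICC120	genbank	OQ263299	Enterococcus durans	NFICC120	ma-gayjn
PrtP_NFICC180	genbank	OQ263300	Leuconostoc pseudomesenteroides	NFICC180
PrtP_NFICC181	genbank	OQ263301	Leuconostoc pseudomesenteroides	NFICC181
PrtP_NFICC200	genbank	OQ263302	Leuconostoc mesenteroides	NFICC200	ma-ioefi
PrtP_NFICC202	genbank	OQ263303	Leuconostoc pseudomesenteroides	NFICC202
PrtP_NFICC227	genbank	OQ263304	Leuconostoc pseudomesenteroides	NFICC227
PrtP_NFICC239	genbank	OQ263305	Leuconostoc mesenteroides	NFICC239
PrtP_NFICC240	genbank	OQ263306	Leuconostoc mesenteroides	NFICC240
PrtP_NFICC313	genbank	OQ263307	Leuconostoc pseudomesenteroides	NFICC313
PrtP_NFICC322	genbank	OQ263308	Leuconostoc pseudomesenteroides	NFICC322
PrtP_NFICC323	genbank	OQ263309	Leuconostoc pseudomesenteroides	NFICC323
PrtP_NFICC476	genbank	OQ263310	Carnobacterium maltaromaticum	NFICC476
PrtP_NFICC546	genbank	OQ263311	Carnobacterium maltaromaticum	NFICC546	ma-ytnir
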