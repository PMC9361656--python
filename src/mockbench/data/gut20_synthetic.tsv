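strain_label	species_name	phylum	family	genus	dsmz_id	gram	genome_size_bp	copies_16s	cell_weight	mass_ng
WC01	Bacteroides fragilis	Bacteroidetes	Bacteroidaceae	Bacteroides	DSM 2151	negative	5205140	6	1	15.62
WC02	Bacteroides vulgatus	Bacteroidetes	Bacteroidaceae	Bacteroides	DSM 1447	negative	5163189	7	1	15.49
WC03	Alistipes finegoldii	Bacteroidetes	Rikenellaceae	Alistipes	DSM 17242	negative	3734239	3	1	11.20
WC04	Prevotella copri	Bacteroidetes	Prevotellaceae	Prevotella	DSM 18205	negative	3512800	3	1	10.54
WC05	Escherichia coli	Proteobacteria	Enterobacteriaceae	Escherichia	DSM 1103	negative	4641652	7	1	13.92
WC06	Escherichia coli	Proteobacteria	Enterobacteriaceae	Escherichia	DSM 30083	negative	5038133	7	1	15.11
WC07	Salmonella enterica	Proteobacteria	Enterobacteriaceae	Salmonella	DSM 17058	negative	4857450	7	1	14.57
WC08	Fusobacterium nucleatum	Fusobacteria	Fusobacteriaceae	Fusobacterium	DSM 15643	negative	2174500	5	1	6.52
WC09	Bifidobacterium adolescentis	Actinobacteria	Bifidobacteriaceae	Bifidobacterium	DSM 20083	positive	2089645	5	1	6.27
WC10	Bifidobacterium longum	Actinobacteria	Bifidobacteriaceae	Bifidobacterium	DSM 20219	positive	2385164	4	1	7.16
WC11	Collinsella aerofaciens	Actinobacteria	Coriobacteriaceae	Collinsella	DSM 3979	positive	2439869	4	1	7.32
WC12	Clostridium butyricum	Firmicutes	Clostridiaceae	Clostridium	DSM 10702	positive	4588039	10	1	13.76
WC13	Clostridium perfringens	Firmicutes	Clostridiaceae	Clostridium	DSM 756	positive	3256683	10	1	9.77
WC14	Clostridioides difficile	Firmicutes	Peptostreptococcaceae	Clostridioides	DSM 1296	positive	4290252	11	1	12.87
WC15	Enterococcus faecalis	Firmicutes	Enterococcaceae	Enterococcus	DSM 20478	positive	2845392	4	1	8.54
WC16	Faecalibacterium prausnitzii	Firmicutes	Ruminococcaceae	Faecalibacterium	DSM 17677	positive	3090955	6	1	9.27
WC17	Ruminococcus gauvreauii	Firmicutes	Lachnospiraceae	Ruminococcus	DSM 19829	positive	4129901	5	1	12.39
WC18	Blautia obeum	Firmicutes	Lachnospiraceae	Blautia	DSM 25238	positive	3622196	4	1	10.87
WC19	Roseburia intestinalis	Firmicutes	Lachnospiraceae	Roseburia	DSM 14610	positive	4410757	6	1	13.23
WC20	Lactobacillus gasseri	Firmicutes	Lactobacillaceae	Lactobacillus	DSM 20243	positive	1894360	6	1	5.68
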