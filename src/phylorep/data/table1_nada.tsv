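phylum	species_strain	complement_aerobic	complement_bssuf	complement_ecsuf	complement_anaerobic	complemented_or_recovered	tir_log10	sds_page	ms_detected	o2_tolerance	temperature_class	fes_system	is_host_control	is_suf_donor
Actinobacteria	Mycolicibacterium smegmatis MC2 155	-	+	+	+	+	3.3	-	+	+	mesophilic	SufBD	0	0
Actinobacteria	Rubrobacter xylanophilus DSM 9941	+	NT	NT	+	+	2.7	-	NT	+	thermophilic	SufBD	0	0
Actinobacteria	Collinsella stercoris DSM 13279	-	-	-	-	-	3.4	-	detection_NT	-	mesophilic	SufBD	0	0
Actinobacteria	Acidimicrobium ferrooxidans DSM 10331	-	+	-	-	+	2.2	-	NT	+	thermophilic	SufBD	0	0
Actinobacteria	Streptomyces cattleya NRRL 8057 = DSM 46488	-	-	-	-	-	4.8	-	+	+	mesophilic	SufBD	0	0
Bacteroidetes	Salinivirga cyanobacteriivorans	+	NT	NT	+	+	NT	+	NT	-	mesophilic	SufBD	0	0
Candidatus Fermentibacteria	Candidatus Fermentibacter daniensis	-	-	-	-	-	3.9	-	detection_NT	-	mesophilic	IscU	0	0
Candidatus Melainabacteria	Candidatus Gastranaerophilales bacterium HUM_7	-	-	-	+	+	3.8	-	NT	-	?	IscU	0	0
Chloroflexi	Sphaerobacter thermophilus DSM 20745	-	+	-	+	+	4.1	-	NT	+	thermophilic	SufBD	0	0
Chloroflexi	Thermogemmatispora tikiterensis	-	-	-	-	-	2.8	-	detection_NT	+	thermophilic	SufBD	0	0
Chrysiogenetes	Desulfurispirillum indicum S5	-	-	-	+	+	3.6	+	NT	-	mesophilic	IscU	0	0
Cyanobacteria	Synechocystis sp. PCC 6803	-	+	-	-	+	3.3	-	NT	+	mesophilic	SufBD	0	0
Cyanobacteria	Crocosphaera watsonii WH 8501	-	+	-	-	+	2.8	-	NT	+	?	SufBD	0	0
Deinococcus-Thermus	Thermus thermophilus HB27	-	+	-	-	+	3.5	-	NT	+	thermophilic	SufBD	0	0
Dictyoglomi	Dictyoglomus thermophilum H-6-12	-	-	-	+	+	3.6	+	NT	-	hyperthermophilic	SufBD,IscU	0	0
Euryarchaeota	Methanopyrus kandleri AV19	-	-	-	-	-	2.9	-	detection_NT	-	hyperthermophilic	SufBD	0	0
Euryarchaeota	Haloferax volcanii DS2	-	-	-	-	-	3.1	-	detection_NT	+	mesophilic	SufBD	0	0
Euryarchaeota	Haloterrigena turkmenica DSM 5511	-	-	-	-	-	3.8	-	detection_NT	+	mesophilic	SufBD	0	0
Euryarchaeota	Candidatus Methanomethylophilus alvus Mx1201	-	-	-	-	-	3.0	-	detection_NT	-	?	SufBD	0	0
Fibrobacteres	Chitinivibrio alkaliphilus ACht1	-	-	-	-	-	3.2	-	detection_NT	-	mesophilic	IscU	0	0
Firmicutes	Bacillus subtilis subsp. subtilis str. 168	-	+	+	+	+	3.8	-	NT	+	mesophilic	SufBD	0	1
Firmicutes	Desulfitobacterium hafniense DCB-2	-	-	-	+	+	3.5	-	+	-	mesophilic	IscU	0	0
Firmicutes	Ruminiclostridium cellulolyticum H10	-	-	-	-	-	2.9	-	detection_NT	-	mesophilic	IscU	0	0
Firmicutes	Heliobacterium modesticaldum Ice1	-	-	-	-	-	3.4	-	+	-	thermophilic	IscU	0	0
Nitrospinae	Nitrospina gracilis	+	NT	NT	+	+	3.2	+	NT	+	mesophilic	SufBD	0	0
Planctomycetes	Gemmata obscuriglobus	+	NT	NT	+	+	2.1	-	NT	+	mesophilic	IscU	0	0
Planctomycetes	Pirellula staleyi DSM 6068	-	-	-	-	-	2.7	-	+	+	mesophilic	SufBD	0	0
Proteobacteria	Aeromonas hydrophila	+	NT	NT	+	+	3.8	-	NT	+	mesophilic	IscU	0	0
Proteobacteria	Desulfovibrio vulgaris str. Hildenborough	-	-	-	-	-	3.2	-	detection_NT	-	mesophilic	SufBD,IscU	0	0
Proteobacteria	Allochromatium vinosum	+	NT	NT	+	+	2.9	+	NT	-	mesophilic	SufBD,IscU(NifU)	0	0
Proteobacteria	Arcobacter butzleri	-	-	-	-	-	2.2	-	+	+	mesophilic	SufBD,IscU	0	0
Proteobacteria	Novosphingobium stygium	-	+	+	-	+	2.3	-	NT	+	mesophilic	SufBD	0	0
Proteobacteria	Herminiimonas arsenicoxydans	+	NT	NT	+	+	3.5	-	NT	+	mesophilic	IscU	0	0
Proteobacteria	Chromobacterium violaceum ATCC 12472	+	NT	NT	+	+	3.4	-	NT	+	mesophilic	IscU	0	0
Proteobacteria	Bdellovibrio bacteriovorus HD100	+	NT	NT	+	+	3.9	-	NT	+	mesophilic	SufBD	0	0
Proteobacteria	Methylobacillus flagellatus KT	-	-	-	-	-	4.7	-	+	-	mesophilic	IscU	0	0
Proteobacteria	Anaeromyxobacter dehalogenans 2 CP-C	+	NT	NT	+	+	3.7	-	NT	-	mesophilic	SufBD,IscU	0	0
Proteobacteria	Candidatus Pelagibacter ubique HTCC1002	-	-	-	-	-	3.4	-	detection_NT	+	?	SufBD	0	0
Proteobacteria	Syntrophobacter fumaroxidans MPOB	-	-	-	-	-	3.5	-	detection_NT	-	mesophilic	SufBD,IscU	0	0
Proteobacteria	Cellvibrio japonicus Ueda107	+	NT	NT	+	+	2.9	-	NT	+	mesophilic	SufBD	0	0
Proteobacteria	Escherichia coli str. K-12 substr. MG1655	+	NT	NT	+	+	3.8	+	+	+	mesophilic	SufBD,IscU	1	0
Proteobacteria	Desulfarculus baarsii DSM 2075	-	-	-	-	-	2.8	-	detection_NT	-	mesophilic	IscU	0	0
Proteobacteria	Salinisphaera sp. LB1	+	NT	NT	+	+	4.0	-	NT	+	mesophilic	SufBD	0	0
Spirochaetes	Leptospira interrogans serovar Lai str. 56,601	+	NT	NT	+	+	4.2	+	NT	+	mesophilic	SufBD	0	0
Spirochaetes	Spirochaeta thermophila DSM 6578	-	+	-	-	+	3.2	-	NT	-	thermophilic	SufBD	0	0
Synergistetes	Thermanaerovibrio acidaminovorans DSM 6589	-	-	-	-	-	NT	-	detection_NT	-	thermophilic	SufBD,IscU	0	0
Thermotogae	Thermotoga maritima MSB8	-	-	-	+	+	4.3	-	NT	-	hyperthermophilic	SufBD	0	0
Verrucomicrobia	Coraliomargarita akajimensis DSM 45221	+	NT	NT	+	+	3.6	+	NT	+	mesophilic	SufBD	0	0
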