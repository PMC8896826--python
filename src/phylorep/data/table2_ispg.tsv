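phylum	species_strain	complement_aerobic	complement_etp	complement_anaerobic	complemented_or_recovered	tir_log10	sds_page	ms_detected	o2_tolerance	temperature_class	fes_system	is_host_control
Acidobacteria	Candidatus Koribacter versatilis Ellin345	-	NT	-	-	3.6	-	detection_NT	+	mesophilic	IscU	0
Actinobacteria	Thermoleophilum album	-	NT	-	-	2.9	-	detection_NT	+	thermophilic	SufBD	0
Actinobacteria	Streptomyces coelicolor A3	-	-	-	-	2.6	-	-	+	mesophilic	SufBD	0
Actinobacteria	Rubrobacter xylanophilus DSM 9941	+	NT	+	+	2.6	-	NT	+	thermophilic	SufBD	0
Actinobacteria	Cutibacterium acnes KPA171202	+	NT	+	+	4.7	-	NT	-	mesophilic	SufBD	0
Actinobacteria	Collinsella stercoris DSM 13279	-	-	+	+	3.3	-	-	-	mesophilic	SufBD	0
Actinobacteria	Acidimicrobium ferrooxidans DSM 10331	+	NT	+	+	3.5	-	NT	+	mesophilic	SufBD	0
Actinobacteria	Streptomyces cattleya NRRL 8057 = DSM 46488	-	+	-	+	2.7	+	NT	+	mesophilic	SufBD	0
Actinobacteria	Egibacter sp.	-	NT	-	-	3.4	-	detection_NT	?	?	SufBD	0
Aquificae	Aquifex aeolicus VF5	+	NT	+	+	3.8	-	NT	+	hyperthermophilic	IscU	0
Aquificae	Thermovibrio ammonificans HB-1	-	NT	-	-	2.9	-	detection_NT	-	thermophilic	SufBD	0
Bacteroidetes	Pedobacter heparinus DSM 2366	-	NT	-	-	NT	-	detection_NT	+	mesophilic	SufBD,IscU	0
Bacteroidetes	Salinivirga cyanobacteriivorans	-	NT	-	-	NT	-	detection_NT	-	mesophilic	SufBD	0
Candidatus Fermentibacteria	Candidatus Fermentibacter daniensis	-	NT	-	-	3.0	-	detection_NT	-	mesophilic	IscU	0
Candidatus Melainabacteria	Candidatus Caenarcanum bioreactoricola	-	NT	-	-	4.1	-	detection_NT	?	?	IscU	0
Candidatus Melainabacteria	Candidatus Gastranaerophilales bacterium HUM_7	-	NT	-	-	4.2	-	detection_NT	-	?	IscU	0
Candidatus Sumerlaeota	Candidatus Sumerlaea chitinovorans	-	NT	-	-	2.9	-	detection_NT	?	?	SufBD	0
Chlamydiae	Chlamydia caviae GPIC	-	-	-	-	2.7	-	-	+	mesophilic	SufBD	0
Chloroflexi	Sphaerobacter thermophilus DSM 20745	-	NT	-	-	NT	-	detection_NT	+	thermophilic	SufBD	0
Cyanobacteria	Gloeobacter violaceus PCC 7421	-	-	-	-	3.6	-	detection_NT	+	?	SufBD	0
Cyanobacteria	Synechocystis sp. PCC 6803	-	+	-	+	3.5	-	NT	+	mesophilic	SufBD	0
Deinococcus-Thermus	Thermus thermophilus HB27	-	-	-	-	2.7	-	-	+	thermophilic	SufBD	0
Fibrobacteres	Fibrobacter succinogenes subsp. succinogenes S85	-	NT	-	-	2.6	-	detection_NT	-	mesophilic	SufBD	0
Firmicutes	Bacillus subtilis subsp. subtilis str. 168	-	+	-	+	2.7	-	NT	+	mesophilic	SufBD	0
Firmicutes	Desulfitobacterium hafniense DCB-2	-	-	-	-	3.4	-	+	-	mesophilic	SufBD	0
Firmicutes	Symbiobacterium thermophilum IAM 14863	-	-	-	-	2.0	-	+	+	thermophilic	SufBD	0
Firmicutes	Ruminiclostridium cellulolyticum H10	-	-	-	-	3.4	-	+	-	mesophilic	IscU	0
Lentisphaerae	Victivallales bacterium CCUG 44730	-	NT	-	-	NT	-	detection_NT	?	?	IscU	0
Nitrospinae	Nitrospina gracilis	-	-	-	-	4.0	-	-	+	mesophilic	SufBD	0
Planctomycetes	Blastopirellula marina DSM 3645	partial	+	+	+	3.1	-	NT	+	mesophilic	SufBD	0
Planctomycetes	Isosphaera pallida ATCC 43644	-	-	-	-	2.5	-	+	+	mesophilic	SufBD	0
Planctomycetes	Phycisphaera mikurensis NBRC 102666	-	NT	-	-	3.8	-	detection_NT	+	mesophilic	SufBD	0
Proteobacteria	Aeromonas hydrophila	+	NT	+	+	2.1	-	NT	+	mesophilic	IscU	0
Proteobacteria	Allochromatium vinosum	-	-	-	-	3.7	-	+	-	mesophilic	SufBD,IscU(NifU)	0
Proteobacteria	Azoarcus sp. BH72	+	NT	+	+	3.1	+	NT	-	mesophilic	IscU	0
Proteobacteria	Helicobacter pylori J99	-	-	+	+	3.3	+	+	+	mesophilic	IscU	0
Proteobacteria	Methylococcus capsulatus str. Bath	+	NT	+	+	3.2	-	NT	+	mesophilic	SufBD,IscU	0
Proteobacteria	Rhodobacter sphaeroides 2.4.1	-	+	-	+	3.4	-	NT	+	mesophilic	SufBD,IscU(NifU)	0
Proteobacteria	Mariprofundus ferrooxydans	-	+	-	+	3.7	-	+	+	mesophilic	SufBD	0
Proteobacteria	Cellvibrio japonicus Ueda107	-	-	-	-	2.6	-	-	+	mesophilic	SufBD	0
Proteobacteria	Escherichia coli str. K-12 substr. MG1655	+	NT	+	+	3.1	+	+	+	mesophilic	SufBD,IscU	1
Proteobacteria	Anaplasma phagocytophilum str. CRT38	-	-	-	-	2.2	-	detection_NT	+	?	IscU	0
Spirochaetes	Spirochaeta thermophila DSM 6578	-	-	-	-	4.0	-	+	-	thermophilic	SufBD	0
Synergistetes	Thermanaerovibrio acidaminovorans DSM 6589	-	NT	-	-	3.1	-	detection_NT	-	thermophilic	SufBD,IscU	0
Tenericutes	Spiroplasma citri	-	NT	-	-	3.0	-	detection_NT	+	mesophilic	SufBD	0
Thermodesulfobacteria	Thermodesulfatator indicus DSM 15286	-	NT	-	-	3.3	-	detection_NT	-	thermophilic	SufBD	0
Thermotogae	Thermotoga maritima MSB8	-	-	+	+	4.4	+	+	-	hyperthermophilic	SufBD	0
Verrucomicrobia	Coraliomargarita akajimensis DSM 45221	-	-	-	-	2.6	-	+	+	mesophilic	SufBD	0
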