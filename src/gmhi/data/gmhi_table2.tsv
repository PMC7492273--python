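#theta_f: 1.4
#theta_d: 0.10
#size_H_eff: 7
#size_N_eff: 43
#presence_threshold: 1e-05
#pseudo_count: 1e-05
#provenance: Packaged 50-species GMHI signature (7 health-prevalent, 43 health-scarce) with discovery prevalences in percent; effective set sizes default to cardinalities because the fitted values were never published.
species	group	p_H	p_N
Alistipes senegalensis	H+	58.5	39.9
Bacteroidales bacterium ph8	H+	73.1	51.4
Bifidobacterium adolescentis	H+	68.2	46.4
Bifidobacterium angulatum	H+	11.9	1.5
Bifidobacterium catenulatum	H+	30.8	13.5
Lachnospiraceae bacterium 8_1_57FAA	H+	44.8	26.9
Sutterella wadsworthensis	H+	48.1	26.2
Anaerotruncus colihominis	H-	23.1	37.4
Atopobium parvulum	H-	2.3	12.7
Bifidobacterium dentium	H-	6.6	16.7
Blautia producta	H-	5.0	15.6
Candidatus Saccharibacteria TM7c	H-	1.9	13.2
Clostridiales bacterium 1_7_47FAA	H-	16.2	40.0
Clostridium asparagiforme	H-	20.8	44.1
Clostridium bolteae	H-	34.5	69.7
Clostridium citroniae	H-	23.9	50.4
Clostridium clostridioforme	H-	9.8	26.1
Clostridium hathewayi	H-	26.9	56.1
Clostridium nexile	H-	14.3	31.7
Clostridium ramosum	H-	10.8	31.9
Clostridium symbiosum	H-	20.9	47.5
Eggerthella lenta	H-	18.9	37.4
Erysipelotrichaceae bacterium 2_2_44A	H-	18.5	33.4
Flavonifractor plautii	H-	34.9	56.5
Fusobacterium nucleatum	H-	2.2	12.3
Gemella morbillorum	H-	1.4	11.7
Gemella sanguinis	H-	5.9	21.0
Granulicatella adiacens	H-	3.4	21.4
Holdemania filiformis	H-	36.9	57.3
Klebsiella pneumoniae	H-	17.4	34.3
Lachnospiraceae bacterium 1_4_56FAA	H-	18.1	38.0
Lachnospiraceae bacterium 2_1_58FAA	H-	33.6	47.1
Lachnospiraceae bacterium 3_1_57FAA_CT1	H-	18.3	35.9
Lachnospiraceae bacterium 5_1_57FAA	H-	6.9	18.9
Lachnospiraceae bacterium 9_1_43BFAA	H-	5.5	16.2
Lactobacillus salivarius	H-	3.8	14.3
Peptostreptococcus stomatis	H-	1.9	13.7
Ruminococcaceae bacterium D16	H-	16.4	31.3
Ruminococcus gnavus	H-	41.8	68.0
Solobacterium moorei	H-	7.4	32.2
Streptococcus anginosus	H-	10.8	30.2
Streptococcus australis	H-	26.9	42.0
Streptococcus gordonii	H-	6.7	22.6
Streptococcus infantis	H-	12.5	28.2
Streptococcus mitis/oralis/pneumoniae	H-	12.3	32.9
Streptococcus sanguinis	H-	14.4	31.9
Streptococcus vestibularis	H-	16.2	30.7
Subdoligranulum sp. 4_3_54A2FAA	H-	5.9	16.7
Subdoligranulum variabile	H-	6.9	17.3
Veillonella atypica	H-	22.5	34.5
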