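node	sub_guild	role	phylum
Corynebacterium_767	ASG	civilian	Actinobacteria
Corynebacterium_1	ASG	civilian	Actinobacteria
Corynebacterium_413	ASG	civilian	Actinobacteria
Corynebacterium_291	ASG	civilian	Actinobacteria
Actinomyces_167	ASG	civilian	Actinobacteria
Capnocytophaga_384	ASG	civilian	Bacteroidetes
Capnocytophaga_252	ASG	civilian	Bacteroidetes
Corynebacterium_633	ASG	guard	Actinobacteria
Corynebacterium_53	ASG	guard	Actinobacteria
Corynebacterium_414	ASG	guard	Actinobacteria
Corynebacterium_256	ASG	guard	Actinobacteria
Corynebacterium_28	ASG	guard	Actinobacteria
Corynebacterium_169	ASG	guard	Actinobacteria
Corynebacterium_304	ASG	guard	Actinobacteria
Actinomyces_500	ASG	guard	Actinobacteria
Actinomyces_436	ASG	guard	Actinobacteria
Bacteria_655	ASG	guard	Others
Fusobacterium_608	ASG	guard	Others
Leptotrichia_615	ASG	guard	Others
Neisseriaceae_683	ASG	guard	Others
valvarum_597	ASG	guard	Others
Rothia_93	FBSG	civilian	Actinobacteria
Rothia_492	FBSG	civilian	Actinobacteria
Rothia_299	FBSG	civilian	Actinobacteria
Actinomyces_426	FBSG	civilian	Actinobacteria
Actinomyces_204	FBSG	civilian	Actinobacteria
Streptococcus_250	FBSG	civilian	Firmicutes
Streptococcus_521	FBSG	civilian	Firmicutes
Veillonellaceae_681	FBSG	civilian	Firmicutes
Veillonellaceae_70	FBSG	civilian	Firmicutes
Veillonella_87	FBSG	civilian	Firmicutes
Mogibacterium_78	FBSG	civilian	Firmicutes
Thermophilus_6	FBSG	civilian	Firmicutes
Prevotella_15	FBSG	civilian	Bacteroidetes
Bacteroidales_88	FBSG	civilian	Bacteroidetes
Prevotella_272	FBSG	civilian	Bacteroidetes
Bacteria_287	FBSG	civilian	Others
Bacteria_469	FBSG	civilian	Others
Salinivibrio_60	FBSG	civilian	Others
Rothia_64	FBSG	guard	Actinobacteria
Rothia_456	FBSG	guard	Actinobacteria
Lactobacillales_246	FBSG	guard	Firmicutes
Lachnospiraceae_89	FBSG	guard	Firmicutes
Peptostreptococcus_4	FBSG	guard	Firmicutes
Streptococcus_452	FBSG	guard	Firmicutes
Veillonellaceae_445	FBSG	guard	Firmicutes
Streptococcus_230	FBSG	guard	Firmicutes
Oribacterium_135	FBSG	guard	Firmicutes
Prevotella_21	FBSG	guard	Bacteroidetes
Prevotella_443	FBSG	guard	Bacteroidetes
pallens_179	FBSG	guard	Bacteroidetes
Prevotella_30	FBSG	guard	Bacteroidetes
Haemophilus_511	FBSG	guard	Others
Enterobacter_236	FBSG	guard	Others
Haemophilus_16	FBSG	guard	Others
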