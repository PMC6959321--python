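name	phylum
Corynebacterium	Actinobacteria
Actinomyces	Actinobacteria
Rothia	Actinobacteria
Atopobium	Actinobacteria
Streptococcus	Firmicutes
Veillonella	Firmicutes
Veillonellaceae	Firmicutes
Mogibacterium	Firmicutes
Thermophilus	Firmicutes
Lactobacillales	Firmicutes
Lachnospiraceae	Firmicutes
Peptostreptococcus	Firmicutes
Oribacterium	Firmicutes
Granulicatella	Firmicutes
Gemella	Firmicutes
Selenomonas	Firmicutes
Prevotella	Bacteroidetes
Capnocytophaga	Bacteroidetes
Bacteroidales	Bacteroidetes
Porphyromonas	Bacteroidetes
pallens	Bacteroidetes
Fusobacterium	Fusobacteria
Leptotrichia	Fusobacteria
Neisseriaceae	Proteobacteria
Neisseria	Proteobacteria
Haemophilus	Proteobacteria
Enterobacter	Proteobacteria
Salinivibrio	Proteobacteria
Campylobacter	Proteobacteria
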