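asg_node	fbsg_node	r	p_value	p_printed
Corynebacterium_414	Rothia_64	-0.677	0.001	<0.001
Corynebacterium_414	Rothia_456	-0.646	0.001	<0.001
Actinomyces_436	Rothia_456	-0.685	0.001	<0.001
Actinomyces_500	Rothia_64	-0.614	0.001	<0.001
Actinomyces_436	Streptococcus_452	-0.696	0.001	<0.001
Actinomyces_436	Oribacterium_135	-0.662	0.001	<0.001
Actinomyces_436	Streptococcus_230	-0.629	0.001	<0.001
Corynebacterium_304	Peptostreptococcus_4	-0.613	0.001	<0.001
Corynebacterium_414	Peptostreptococcus_4	-0.643	0.001	<0.001
Corynebacterium_414	Streptococcus_452	-0.636	0.001	<0.001
Corynebacterium_414	Streptococcus_230	-0.653	0.001	<0.001
Actinomyces_500	Lactobacillales_246	-0.626	0.001	<0.001
Actinomyces_500	Veillonellaceae_445	-0.607	0.001	<0.001
Corynebacterium_414	Lachnospiraceae_89	-0.614	0.001	<0.001
Corynebacterium_633	Streptococcus_230	-0.608	0.001	<0.001
Corynebacterium_256	Streptococcus_230	-0.673	0.001	<0.001
Corynebacterium_414	Oribacterium_135	-0.606	0.001	0.001
Actinomyces_500	Prevotella_443	-0.629	0.001	<0.001
Actinomyces_500	Prevotella_30	-0.624	0.001	<0.001
Corynebacterium_169	pallens_179	-0.658	0.001	<0.001
Corynebacterium_53	pallens_179	-0.621	0.001	<0.001
Corynebacterium_28	pallens_179	-0.610	0.001	<0.001
Corynebacterium_256	pallens_179	-0.607	0.001	<0.001
Corynebacterium_414	Haemophilus_16	-0.652	0.001	<0.001
Actinomyces_500	Haemophilus_511	-0.624	0.001	<0.001
Neisseriaceae_683	pallens_179	-0.620	0.001	<0.001
Neisseriaceae_683	Prevotella_443	-0.608	0.001	<0.001
Neisseriaceae_683	Prevotella_21	-0.604	0.001	0.001
Bacteria_655	pallens_179	-0.737	0.001	<0.001
valvarum_597	pallens_179	-0.657	0.001	<0.001
Leptotrichia_615	pallens_179	-0.647	0.001	<0.001
Neisseriaceae_683	Streptococcus_230	-0.759	0.001	<0.001
Neisseriaceae_683	Lactobacillales_246	-0.605	0.001	0.001
Neisseriaceae_683	Streptococcus_452	-0.602	0.001	0.001
valvarum_597	Streptococcus_452	-0.618	0.001	<0.001
valvarum_597	Streptococcus_230	-0.615	0.001	<0.001
Bacteria_655	Streptococcus_230	-0.612	0.001	<0.001
Fusobacterium_608	Enterobacter_236	-0.619	0.001	<0.001
Neisseriaceae_683	Haemophilus_511	-0.691	0.001	<0.001
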