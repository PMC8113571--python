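motif_class	total	primer_designed	proximal_removed	at_only_removed	pursued	called	mono_or_missing_removed	low_nonref_removed	polymorphic
Di	17299	15459	675	6640	8144	6729	4021	701	2007
Tri	13100	11072	391	4847	5834	4963	2328	660	1975
Tetra	5925	4022	40	2349	1633	1427	803	188	436
Penta	3659	2935	445	477	2013	1613	813	198	602
Hexa	2172	2079	53	253	1773	1447	336	145	966
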