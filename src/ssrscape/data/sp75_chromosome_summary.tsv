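chromosome	length_bp	n_ssr	n_polymorphic
Chr01	50662332	5200	862
Chr02	60576128	5444	820
Chr03	113461288	10269	1277
Chr04	122945393	10737	1529
Chr05	69506562	5649	777
Chr06	46407490	4856	721
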