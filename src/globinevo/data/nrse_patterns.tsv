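# Default neuron-restrictive silencer element (NRSE/RE-1) consensus patterns.
# The 21-bp element bound by REST/NRSF; the first entry is the classic
# experimentally derived consensus, the second a degenerate IUPAC variant
# covering reported site heterogeneity. Patterns are configuration data:
# replace or extend this file to scan your own consensi.
# name	iupac	max_mismatches
NRSE_21	TTCAGCACCACGGACAGCGCC	0
NRSE_21_degenerate	NTYAGMRCCNNRGMSAGNRMC	0
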