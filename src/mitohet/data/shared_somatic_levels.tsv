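# Published multi-tissue heteroplasmy levels (percentage of the rCRS-non-reference
# nucleotide) for somatic point mutations observed in more than one tissue sample of
# the same patient, from a 28-patient oral squamous cell carcinoma cohort sequenced
# at ~35,000x mitochondrial coverage.  "n.a." = tissue not available; "n.d." = not
# detected above the 1% dual-strand threshold.
patient	mutation	benign	blood	primary_tumor	recurrence	lymph_node_metastasis
MKG05	m.C64Y	n.d.	n.d.	12.13	62.3	n.a.
MKG05	m.A5894R	n.d.	n.d.	15.54	71.6	n.a.
MKG05	m.G6762R	n.d.	n.d.	7.14	1.2	n.a.
MKG05	m.G10310R	n.d.	n.d.	10.8	61.2	n.a.
MKG10	m.T9865Y	n.d.	n.a.	1.76	1.6	n.a.
MKG15	m.C5297Y	n.d.	n.a.	45.87	n.a.	84.8
MKG15	m.G9565R	n.d.	n.a.	12.41	n.a.	55.1
MKG15	m.G12868R	n.d.	n.a.	37.8	n.a.	85.8
MKG20	m.G2916R	n.d.	n.a.	21.02	n.a.	31.5
MKG20	m.G12736R	n.d.	n.a.	24.73	n.a.	32
MKG27	m.A183R	n.d.	n.a.	22.7	n.a.	57.5
MKG27	m.T13897Y	n.d.	n.a.	2.4	n.a.	1.9
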