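# Published multi-tissue heteroplasmy levels (percentage of the rCRS-non-reference
# nucleotide) for point mutations shared between benign and cancerous tissue samples
# of the same patient and therefore considered germline, from the same 28-patient
# oral squamous cell carcinoma cohort as shared_somatic_levels.tsv.
# "n.a." = tissue not available; "n.d." = not detected above the 1% threshold.
patient	mutation	benign	blood	primary_tumor	recurrence	lymph_node_metastasis
MKG01	m.G14560R	1.65	n.a.	1.38	n.a.	n.a.
MKG04	m.T5789Y	16.91	45.62	8.21	n.a.	n.a.
MKG05	m.C16261Y	1.27	n.d.	87.02	74.8	n.a.
MKG06	m.G8865R	27.74	20.86	65.87	n.a.	n.a.
MKG07	m.T16093Y	22.39	n.a.	10.58	n.a.	n.a.
MKG08	m.G15355R	52.08	56.66	10.37	n.a.	n.a.
MKG11	m.T146Y	98.73	45.16	n.a.	n.a.	n.a.
MKG13	m.C13287Y	3.53	n.a.	1.38	1.7	n.a.
MKG13	m.T5814Y	6.73	n.a.	4.15	5.3	n.a.
MKG15	m.A9794R	2.84	n.a.	1.63	n.a.	74.7
MKG17	m.G15498R	23.73	n.a.	30.5	n.a.	n.a.
MKG21	m.G13759R	2.66	n.a.	1.26	1.54	n.a.
MKG21	m.C16465Y	89.32	n.a.	41.85	43.35	n.a.
MKG22	m.C16148Y	30.5	n.a.	6.17	n.a.	n.a.
MKG23	m.T4597Y	1.28	n.a.	1.3	n.a.	n.a.
MKG27	m.A16241R	1.1	n.a.	1.14	n.a.	n.d.
MKG27	m.A9702R	8.6	n.a.	25.4	n.a.	58.9
MKG27	m.A215R	24	n.a.	32.5	n.a.	56.7
MKG28	m.C64Y	6.83	n.a.	3.33	n.a.	n.a.
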