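# TBP-site position count matrix, 15 positions (columns A C G T).
# Core rows 1-8 carry the canonical TATA consensus TATAWAWR; rows 9-15
# describe the mildly G/C-enriched context immediately downstream.
A	C	G	T
5	5	5	85
85	5	5	5
5	4	2	89
90	2	3	5
52	3	3	42
80	4	6	10
50	4	4	42
50	3	43	4
15	38	28	19
18	28	36	18
16	35	29	20
20	27	38	15
17	36	28	19
21	29	37	13
18	37	27	18
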