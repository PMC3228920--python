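base	1 (8)	2 (7)	3 (6)	4 (5)
A	634	156	721	37
C	6	25	84	573
G	135	560	27	4
T	57	91	0	218
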