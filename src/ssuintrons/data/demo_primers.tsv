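# Demo primer list for end-to-end runs; sequences are drawn from the
# packaged reference (exact or lightly degenerate). Real primer
# catalogs are user-supplied input in the same 3-column format.
name	sequence	orientation
demo500F	CAGCTACGCGAGCAATGTGT	F
demo770F	TTACCGGTGCATGGAAGTGG	F
demo900R	GCGCGAGCGCCATTCCCGGC	R
demo1200F	GGRACGGACNAGGTGGTGGG	F
demo1380F	CCGACGGCGGGCAGCCTCCT	F
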