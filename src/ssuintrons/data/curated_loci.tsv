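# Curated per-locus intron inventory (insertion locus = position directly before
# the insertion point, reference numbering). cds = homing-endonuclease coding
# sequences at the locus; motifs1/motifs2 = of those, number with one / two
# LAGLIDADG motif copies; hp = short (<50 nt) hairpin introns; pru = partial,
# remnant, or uncharacterized introns. primers = names of "universal" primers
# whose annealing footprint spans the locus (semicolon separated, '-' if none).
# ambiguous=1 marks rows whose hp/pru split is typographically uncertain in the
# source table; counts there are a best-effort reading.
locus	cds	motifs1	motifs2	hp	pru	primers	ambiguous
374	5	5	0	1	0	Kb366F	1
548	2	0	2	13	0	-	0
722	0	0	0	0	2	-	0
781	14	2	4	0	28	Ab779F	0
803	0	0	0	0	3	Ab789F;Arc806R	0
901	0	0	0	8	0	Ab909R	0
908	4	1	3	0	6	Ab909R;Ab906F;926wF;U926R;Ab927R	0
919	6	2	3	2	7	Ab906F;926wF;U926R;Ab927R;A934R	1
978	0	0	0	9	0	-	0
1093	15	4	11	7	9	-	1
1205	2	0	2	17	0	-	0
1213	18	4	14	0	2	-	0
1391	15	7	2	0	5	UA1406R;N1406R;U1406R	0
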