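# Hypervariable-region intervals (V1-V9) on the packaged 1542-nt coordinate frame.
# Coordinates are 1-based inclusive. Intervals follow commonly cited E. coli-frame
# boundaries (Chakravorty et al. 2007, J Microbiol Methods 69:330-339, approx.).
name	start	end	source
V1	69	99	chakravorty2007
V2	137	242	chakravorty2007
V3	433	497	chakravorty2007
V4	576	682	chakravorty2007
V5	822	879	chakravorty2007
V6	986	1043	chakravorty2007
V7	1117	1173	chakravorty2007
V8	1243	1294	chakravorty2007
V9	1435	1465	chakravorty2007
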