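pdb_id	uniprot	geom_score	area	ace	transform
1BL4	FKB1A	1328	451.7	-346.89	0.29948 -0.52512 -2.66923 20.02024 12.12580 7.65261
1DB1	VDR	2190	396.9	-402.49	2.24124 -1.12599 2.08615 -5.02815 24.92850 41.97212
1ICE	CASP1	1290	490.5	-456.81	3.10960 -0.49380 -0.04148 32.33943 52.00560 4.29316
1NMS	CASP3	1624	387.5	-378.14	-0.03535 0.04862 -2.03367 25.21819 13.04502 -9.84853
1PW6	IL2	1720	416.1	-439.09	2.19306 -0.53308 -2.49690 88.10656 30.51603 35.60994
1NXK	P49137	1486	386.8	-484.19	0.26065 1.01573 0.40363 90.77334 9.18137 30.57505
1TFG	TGFB2	3130	346.8	-418.27	0.08687 -0.05031 1.92449 4.06230 37.50500 15.50360
1MQ6	FA10	1300	375.8	-459.61	2.51453 -0.37431 -2.92742 48.50947 3.03372 38.24805
2PE1	PDPK1	1896	461.9	-562.56	-1.77023 0.24687 -2.06069 6.90130 65.74122 28.98557
2RGS	Q16539	1568	455.9	-614.34	2.30613 -1.44196 1.32929 37.41191 -15.10245 31.61810
3C4C	BRAF1	1472	427.3	-488.98	-2.95557 0.19922 -0.83340 -13.00394 17.30278 -0.55134
3FV8	P53779	1366	450.6	-429.62	-1.18766 0.46462 2.66234 -24.40976 -7.18411 1.10192
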