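pdb_id	uniprot	geom_score	area	ace	transform
1BL4	FKB1A	1950	319.5	-341.15	-1.80502 -1.44915 -1.71611 6.51155 15.99134 27.83651
1BMQ	CASP1	2334	468.1	-494.43	0.86276 0.14930 2.82708 46.73998 50.95963 1.73014
1DB1	VDR	3352	454.5	-392.19	2.55973 -1.10036 0.31187 30.63651 19.85716 62.65453
1GS4	ANDR	1850	363.7	-386.21	-1.81837 0.56780 2.82529 9.23109 9.66646 8.71106
1IG1	DAPK1	1226	427.5	-459.77	-0.88438 0.47386 -0.32604 20.06074 25.86862 24.02309
1KV2	Q16539	1502	451.9	-526.44	-2.86728 -0.26009 0.78648 -2.20249 17.37292 15.16249
1PMN	MK10	2156	474.4	-480.14	0.60624 -0.97594 3.08589 30.23789 2.45222 17.30323
1PY2	IL2	1478	386.5	-431.36	3.13434 0.15769 -1.67019 16.50101 11.89488 74.45355
1RHJ	CASP3	2770	391.2	-326.53	-2.38764 0.21897 -0.92565 -116.92443 16.34730 80.13059
1S9J	MP2K1	1272	378.3	-462.76	-0.07504 0.18569 -2.51140 45.68630 56.41451 15.15250
1NXK	P49137	1958	476.7	-456.24	-2.84526 -0.79813 1.53759 129.57735 31.92929 56.63747
2JRI	FA10	2920	448.1	-368.14	-0.87237 -1.09567 1.46741 -11.67501 -17.26502 6.80250
2PEI	PDPK1	1660	445.9	-547	-0.59030 0.87216 0.49408 -2.14150 55.95997 24.91314
2YXJ	Q07817	1612	421.3	-462.2	0.41523 -0.28987 -2.46397 9.62220 -25.11701 -2.64235
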