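# Published top-20 meta-gene lists for the macular and non-macular AMD RPE/choroid
# contrasts: signed Fisher statistic F_g (negative = up-regulated by the reporting
# convention) and the printed BH-adjusted combined p-value, kept as the original
# string so the printed precision is known.  Used by crossde.reference for
# internal-consistency checks of the Fisher / chi-square(4) / BH arithmetic.
region	entrez	symbol	fg	p_printed	effect
macular	84624	FNDC1	-47.991	1.72e-05	Up-regulated
macular	4060	LUM	-46.502	1.75e-05	Up-regulated
macular	131578	LRRC15	-40.042	0.00019	Up-regulated
macular	5803	PTPRZ1	-38.086	0.00032	Up-regulated
macular	9547	CXCL14	-38.22	0.00032	Up-regulated
macular	8148	TAF15	-35.072	0.00102	Up-regulated
macular	4804	NGFR	-34.669	0.00109	Up-regulated
macular	3381	IBSP	-31.756	0.00272	Up-regulated
macular	3371	TNC	-31.912	0.00272	Up-regulated
macular	1118	CHIT1	-31.852	0.00272	Up-regulated
macular	1515	CTSV	-31.612	0.00272	Up-regulated
macular	84466	MEGF10	-31.106	0.00278	Up-regulated
macular	2224	FDPS	-31.247	0.00278	Up-regulated
macular	6695	SPOCK1	-30.827	0.00287	Up-regulated
macular	55827	DCAF6	40.05	0.00019	Down-regulated
macular	64093	SMOC1	37.387	0.00039	Down-regulated
macular	7066	THPO	31.517	0.00272	Down-regulated
macular	100128731	OST4	31.747	0.00272	Down-regulated
macular	2619	GAS1	32.158	0.00272	Down-regulated
macular	83473	KATNAL2	31.124	0.00278	Down-regulated
nonmacular	54108	CHRAC1	-40.355	0.00066	Up-regulated
nonmacular	10648	SCGB1D1	-36.412	0.00216	Up-regulated
nonmacular	64116	SLC39A8	-31.469	0.00826	Up-regulated
nonmacular	84656	GLYR1	-30.629	0.00826	Up-regulated
nonmacular	79095	C9orf16	-30.731	0.00826	Up-regulated
nonmacular	6422	SFRP1	-28.224	0.01414	Up-regulated
nonmacular	1974	EIF4A2	32.756	0.0081	Down-regulated
nonmacular	58155	PTBP2	30.667	0.00826	Down-regulated
nonmacular	400073	C12orf76	31.225	0.00826	Down-regulated
nonmacular	146225	CMTM2	29.187	0.0118	Down-regulated
nonmacular	65982	ZSCAN18	29.314	0.0118	Down-regulated
nonmacular	23564	DDAH2	29.244	0.0118	Down-regulated
nonmacular	115761	ARL11	28.924	0.01223	Down-regulated
nonmacular	6404	SELPLG	27.816	0.01414	Down-regulated
nonmacular	84695	LOXL3	27.903	0.01414	Down-regulated
nonmacular	8936	WASF1	27.635	0.01414	Down-regulated
nonmacular	8675	STX16	27.52	0.01414	Down-regulated
nonmacular	8803	SUCLA2	27.535	0.01414	Down-regulated
nonmacular	54816	ZNF280D	28.257	0.01414	Down-regulated
nonmacular	3187	HNRNPH1	27.798	0.01414	Down-regulated
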