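scheme	code	group	suppressed
corine	111	Artificial surfaces	0
corine	112	Artificial surfaces	0
corine	121	Artificial surfaces	0
corine	122	Artificial surfaces	0
corine	123	Artificial surfaces	0
corine	124	Artificial surfaces	0
corine	131	Artificial surfaces	0
corine	132	Artificial surfaces	0
corine	133	Artificial surfaces	0
corine	141	Artificial surfaces	0
corine	142	Artificial surfaces	0
corine	211	Agricultural areas	0
corine	212	Agricultural areas	0
corine	213	Agricultural areas	0
corine	221	Agricultural areas	0
corine	222	Agricultural areas	0
corine	223	Agricultural areas	0
corine	231	Agricultural areas	0
corine	241	Agricultural areas	0
corine	242	Agricultural areas	0
corine	243	Agricultural areas	0
corine	244	Agricultural areas	0
corine	311	Forest and seminatural areas	0
corine	312	Forest and seminatural areas	0
corine	313	Forest and seminatural areas	0
corine	321	Forest and seminatural areas	0
corine	322	Forest and seminatural areas	0
corine	323	Forest and seminatural areas	0
corine	324	Forest and seminatural areas	0
corine	331	Forest and seminatural areas	0
corine	332	Forest and seminatural areas	0
corine	333	Forest and seminatural areas	0
corine	334	Forest and seminatural areas	0
corine	335	Forest and seminatural areas	0
corine	411	Wetlands	1
corine	412	Wetlands	1
corine	421	Wetlands	1
corine	422	Wetlands	1
corine	423	Wetlands	1
corine	511	Water bodies	0
corine	512	Water bodies	0
corine	521	Water bodies	0
corine	522	Water bodies	0
corine	523	Water bodies	0
esacci	10	Cropland, rainfed + Mosaic cropland	0
esacci	11	Cropland, rainfed + Mosaic cropland	0
esacci	12	Cropland, rainfed + Mosaic cropland	0
esacci	20	Other	1
esacci	30	Cropland, rainfed + Mosaic cropland	0
esacci	40	Natural vegetation	0
esacci	50	Other	1
esacci	60	Natural vegetation	0
esacci	61	Other	1
esacci	62	Other	1
esacci	70	Natural vegetation	0
esacci	71	Other	1
esacci	72	Other	1
esacci	80	Other	1
esacci	81	Other	1
esacci	82	Other	1
esacci	90	Natural vegetation	0
esacci	100	Natural vegetation	0
esacci	110	Other	1
esacci	120	Natural vegetation	0
esacci	121	Other	1
esacci	122	Other	1
esacci	130	Natural vegetation	0
esacci	140	Other	1
esacci	150	Natural vegetation	0
esacci	151	Other	1
esacci	152	Other	1
esacci	153	Other	1
esacci	160	Other	1
esacci	170	Other	1
esacci	180	Natural vegetation	0
esacci	190	Urban areas	0
esacci	200	Bare areas	1
esacci	201	Bare areas	1
esacci	202	Bare areas	1
esacci	210	Water	1
esacci	220	Other	1
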