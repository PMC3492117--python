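locus_tag	category
Cthe_3077	Non-catalytic cellulosomal proteins
Cthe_3078	Non-catalytic cellulosomal proteins
Cthe_3079	Non-catalytic cellulosomal proteins
Cthe_3080	Non-catalytic cellulosomal proteins
Cthe_1307	Non-catalytic cellulosomal proteins
Cthe_0452	Non-catalytic cellulosomal proteins
Cthe_0736	Non-catalytic cellulosomal proteins
Cthe_0625	Cellulosomal glycosidases
Cthe_0745	Cellulosomal glycosidases
Cthe_0821	Cellulosomal glycosidases
Cthe_2761	Cellulosomal glycosidases
Cthe_0275	Non-cellulosomal glycosidases
Cthe_1221	Non-cellulosomal glycosidases
Cthe_1777	Non-cellulosomal glycosidases
Cthe_1787	Non-cellulosomal glycosidases
Cthe_1911	Non-cellulosomal glycosidases
Cthe_2548	Non-cellulosomal glycosidases
Cthe_2807	Non-cellulosomal glycosidases
Cthe_2809	Non-cellulosomal glycosidases
Cthe_2989	Non-cellulosomal glycosidases
Cthe_3063	Non-cellulosomal glycosidases
Cthe_3163	Non-cellulosomal glycosidases
Cthe_0059	RsgI-like sigma factors and anti-sigma-I factors
Cthe_0267	RsgI-like sigma factors and anti-sigma-I factors
Cthe_2521	RsgI-like sigma factors and anti-sigma-I factors
Cthe_0391	Cello-oligosaccharide ABC transporters
Cthe_0392	Cello-oligosaccharide ABC transporters
Cthe_0393	Cello-oligosaccharide ABC transporters
Cthe_1018	Cello-oligosaccharide ABC transporters
Cthe_1019	Cello-oligosaccharide ABC transporters
Cthe_1020	Cello-oligosaccharide ABC transporters
Cthe_1862	Cello-oligosaccharide ABC transporters
Cthe_2128	Cello-oligosaccharide ABC transporters
Cthe_2446	Cello-oligosaccharide ABC transporters
Cthe_0137	Glycolysis
Cthe_0138	Glycolysis
Cthe_0139	Glycolysis
Cthe_0140	Glycolysis
Cthe_0217	Glycolysis
Cthe_0349	Glycolysis
Cthe_0389	Glycolysis
Cthe_0390	Glycolysis
Cthe_0707	Glycolysis
Cthe_0946	Glycolysis
Cthe_1261	Glycolysis
Cthe_1292	Glycolysis
Cthe_2938	Glycolysis
Cthe_2443	Pentose phosphate pathway
Cthe_2444	Pentose phosphate pathway
Cthe_2704	Pentose phosphate pathway
Cthe_2705	Pentose phosphate pathway
Cthe_0282	Energy storage
Cthe_1284	Energy storage
Cthe_3166	Energy storage
Cthe_3167	Energy storage
Cthe_2390	End-product synthesis from pyruvate
Cthe_2391	End-product synthesis from pyruvate
Cthe_2392	End-product synthesis from pyruvate
Cthe_2393	End-product synthesis from pyruvate
Cthe_0423	End-product synthesis from pyruvate
Cthe_0428	End-product synthesis from pyruvate
Cthe_0429	End-product synthesis from pyruvate
Cthe_0430	End-product synthesis from pyruvate
Cthe_0342	End-product synthesis from pyruvate
Cthe_3003	End-product synthesis from pyruvate
Cthe_2794	End-product synthesis from pyruvate
Cthe_2795	End-product synthesis from pyruvate
Cthe_2796	End-product synthesis from pyruvate
Cthe_2797	End-product synthesis from pyruvate
Cthe_3120	End-product synthesis from pyruvate
Cthe_0866	End-product synthesis from pyruvate
Cthe_0614	End-product synthesis from pyruvate
Cthe_0505	End-product synthesis from pyruvate
Cthe_0506	End-product synthesis from pyruvate
Cthe_0647	End-product synthesis from pyruvate
Cthe_1167	End-product synthesis from pyruvate
Cthe_1578	End-product synthesis from pyruvate
Cthe_2602	Energy generation
Cthe_2603	Energy generation
Cthe_2604	Energy generation
Cthe_2605	Energy generation
Cthe_2606	Energy generation
Cthe_2607	Energy generation
Cthe_2608	Energy generation
Cthe_2609	Energy generation
Cthe_2262	Energy generation
Cthe_2263	Energy generation
Cthe_2264	Energy generation
Cthe_2265	Energy generation
Cthe_2266	Energy generation
Cthe_2267	Energy generation
Cthe_2268	Energy generation
Cthe_2269	Energy generation
Cthe_3019	Energy generation
Cthe_3020	Energy generation
Cthe_3021	Energy generation
Cthe_3022	Energy generation
Cthe_3023	Energy generation
Cthe_3024	Energy generation
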