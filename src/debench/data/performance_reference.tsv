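scenario	method	fdr	ns	fpr	tpr
I	DESeq	0.1	759	0.0090	0.6779
I	DESeq	0.05	679	0.0054	0.6304
I	DESeq	0.01	550	0.0020	0.5316
I	edgeR	0.1	825	0.0115	0.7216
I	edgeR	0.05	740	0.0068	0.6799
I	edgeR	0.01	614	0.0023	0.5934
I	DEGseq	0.1	8814	0.8735	0.9532
I	DEGseq	0.05	8864	0.8573	0.8573
I	DEGseq	0.01	8415	0.8306	0.9402
I	NBPSeq	0.1	1167	0.0480	0.7346
I	NBPSeq	0.05	972	0.0322	0.6828
I	NBPSeq	0.01	723	0.0153	0.5850
I	baySeq	0.1	729	0.0060	0.6750
I	baySeq	0.05	654	0.0027	0.6296
I	baySeq	0.01	543	0.0006	0.5384
I	TSPM	0.1	2307	0.1687	0.7893
I	TSPM	0.05	1815	0.0120	0.7306
I	TSPM	0.01	1202	0.0663	0.6050
II	DESeq	0.1	289	0.0153	0.1515
II	DESeq	0.05	175	0.0096	0.0890
II	DESeq	0.01	59	0.0037	0.0255
II	edgeR	0.1	239	0.0138	0.1139
II	edgeR	0.05	130	0.0080	0.0580
II	edgeR	0.01	38	0.0028	0.0127
II	DEGseq	0.1	8379	0.8292	0.9162
II	DEGseq	0.05	8215	0.8119	0.9081
II	DEGseq	0.01	7921	0.7801	0.8923
II	NBPSeq	0.1	308	0.0207	0.1219
II	NBPSeq	0.05	194	0.0134	0.0729
II	NBPSeq	0.01	70	0.0054	0.0213
II	baySeq	0.1	189	0.0070	0.1260
II	baySeq	0.05	88	0.0029	0.0617
II	baySeq	0.01	10	0.0003	0.0067
II	TSPM	0.1	291	0.0262	0.0557
II	TSPM	0.05	262	0.0234	0.0513
II	TSPM	0.01	217	0.0191	0.0447
III	DESeq	0.1	363	0.0056	0.6200
III	DESeq	0.05	319	0.0034	0.5739
III	DESeq	0.01	255	0.0013	0.4860
III	edgeR	0.1	401	0.0068	0.6729
III	edgeR	0.05	354	0.0041	0.6301
III	edgeR	0.01	284	0.0014	0.5414
III	DEGseq	0.1	8451	0.8391	0.9598
III	DEGseq	0.05	8288	0.8222	0.9555
III	DEGseq	0.01	8002	0.7925	0.9462
III	NBPSeq	0.1	567	0.0241	0.6767
III	NBPSeq	0.05	474	0.0169	0.6283
III	NBPSeq	0.01	346	0.0084	0.5335
III	baySeq	0.1	332	0.0031	0.6052
III	baySeq	0.05	295	0.0015	0.5615
III	baySeq	0.01	242	0.0004	0.4763
III	TSPM	0.1	851	0.0529	0.6892
III	TSPM	0.05	651	0.0354	0.6311
III	TSPM	0.01	426	0.018	0.5035
IV	DESeq	0.1	758	0.0090	0.6770
IV	DESeq	0.05	678	0.0055	0.6290
IV	DESeq	0.01	544	0.0019	0.5269
IV	edgeR	0.1	828	0.0117	0.7225
IV	edgeR	0.05	739	0.0068	0.6780
IV	edgeR	0.01	613	0.0023	0.5923
IV	DEGseq	0.1	9326	0.9297	0.9592
IV	DEGseq	0.05	9081	0.9035	0.9494
IV	DEGseq	0.01	8812	0.8748	0.9384
IV	NBPSeq	0.1	1860	0.1252	0.7333
IV	NBPSeq	0.05	1299	0.0707	0.6622
IV	NBPSeq	0.01	792	0.0277	0.5423
IV	baySeq	0.1	728	0.0066	0.6686
IV	baySeq	0.05	653	0.0032	0.634
IV	baySeq	0.01	540	0.0008	0.5332
IV	TSPM	0.1	7387	0.3374	0.7515
IV	TSPM	0.05	3005	0.2575	0.6879
IV	TSPM	0.01	1931	0.1524	0.5593
V	DESeq	0.1	686	0.0084	0.6103
V	DESeq	0.05	611	0.0050	0.5663
V	DESeq	0.01	494	0.0018	0.4779
V	edgeR	0.1	747	0.0107	0.6507
V	edgeR	0.05	667	0.0062	0.6109
V	edgeR	0.01	549	0.0020	0.5315
V	DEGseq	0.1	8763	0.8685	0.9454
V	DEGseq	0.05	8609	0.8520	0.9411
V	DEGseq	0.01	8354	0.8247	0.9312
V	NBPSeq	0.1	1049	0.0431	0.6612
V	NBPSeq	0.05	878	0.0293	0.6142
V	NBPSeq	0.01	648	0.0139	0.5226
V	baySeq	0.1	667	0.0055	0.6186
V	baySeq	0.05	598	0.0026	0.5746
V	baySeq	0.01	493	0.0006	0.4886
V	TSPM	0.1	2072	0.1488	0.7324
V	TSPM	0.05	1617	0.1047	0.6747
V	TSPM	0.01	1072	0.0575	0.5544
VI	DESeq	0.1	789	0.0086	0.6816
VI	DESeq	0.05	679	0.0051	0.6331
VI	DESeq	0.01	547	0.0018	0.5305
VI	edgeR	0.1	825	0.0106	0.7301
VI	edgeR	0.05	741	0.0060	0.6869
VI	edgeR	0.01	615	0.002	0.5975
VI	DEGseq	0.1	8811	0.8721	0.9618
VI	DEGseq	0.05	8675	0.8576	0.9567
VI	DEGseq	0.01	8436	0.8318	0.9493
VI	NBPSeq	0.1	1070	0.0380	0.7283
VI	NBPSeq	0.05	910	0.0256	0.6790
VI	NBPSeq	0.01	689	0.022	0.5788
VI	baySeq	0.1	722	0.0055	0.6727
VI	baySeq	0.05	646	0.0023	0.6254
VI	baySeq	0.01	535	0.0005	0.5310
VI	TSPM	0.1	1920	0.1277	0.7711
VI	TSPM	0.05	1485	0.0086	0.7067
VI	TSPM	0.01	950	0.0418	0.5736
VII	DESeq	0.1	233	0.0125	0.1211
VII	DESeq	0.05	144	0.0080	0.0725
VII	DESeq	0.01	53	0.0034	0.0220
VII	edgeR	0.1	200	0.0121	0.0913
VII	edgeR	0.05	109	0.0070	0.0457
VII	edgeR	0.01	34	0.0026	0.0106
VII	DEGseq	0.1	8429	0.8346	0.9184
VII	DEGseq	0.05	8255	0.8163	0.9091
VII	DEGseq	0.01	7949	0.7840	0.8929
VII	NBPSeq	0.1	253	0.0170	0.0991
VII	NBPSeq	0.05	153	0.0108	0.0562
VII	NBPSeq	0.01	59	0.0047	0.0165
VII	baySeq	0.1	156	0.0054	0.1076
VII	baySeq	0.05	70	0.0021	0.0508
VII	baySeq	0.01	7	0.0002	0.0047
VII	TSPM	0.1	296	0.0024	0.0571
VII	TSPM	0.05	266	0.0236	0.0537
VII	TSPM	0.01	219	0.0191	0.0476
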