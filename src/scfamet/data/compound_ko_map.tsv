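compound_id	ko_id	class
C00033	K00925	SCFA
C00033	K00625	SCFA
C00033	K01895	SCFA
C00033	K01034	SCFA
C00033	K01035	SCFA
C00033	K13788	SCFA
C00033	K04020	SCFA
C00246	K00929	SCFA
C00246	K01034	SCFA
C00246	K01035	SCFA
C00246	K00634	SCFA
C00246	K00248	SCFA
C00163	K01026	SCFA
C00163	K00932	SCFA
C00163	K13923	SCFA
C00163	K01908	SCFA
C00022	K00175	SCFA
C00022	K03737	SCFA
C00022	K01006	SCFA
C00022	K01653	SCFA
C00022	K01652	SCFA
C00022	K00016	SCFA
C00022	K01752	SCFA
C00022	K01738	SCFA
C00022	K00873	SCFA
C00022	K01007	SCFA
C00024	K00175	SCFA
C00024	K03737	SCFA
C00024	K01647	SCFA
C00024	K15023	SCFA
C00024	K00625	SCFA
C00024	K01895	SCFA
C00024	K00626	SCFA
C00024	K01026	SCFA
C00136	K00248	SCFA
C00136	K00074	SCFA
C00136	K01715	SCFA
C00136	K00634	SCFA
C00136	K01034	SCFA
C00186	K00016	SCFA
C00186	K00101	SCFA
C00186	K03777	SCFA
C00042	K00239	SCFA
C00042	K00240	SCFA
C00042	K01902	SCFA
C00042	K01903	SCFA
C00042	K18118	SCFA
C02632	K00166	BCFA
C02632	K00167	BCFA
C02632	K00826	BCFA
C02632	K01652	BCFA
C02632	K01653	BCFA
C02632	K00382	BCFA
C00803	K00128	BCFA
C00803	K00248	BCFA
C00803	K01897	BCFA
C08262	K00253	BCFA
C08262	K00826	BCFA
C08262	K01968	BCFA
C08262	K01969	BCFA
C08262	K00382	BCFA
C21399	K01702	BCFA
C21399	K01703	BCFA
C21399	K00052	BCFA
C21399	K00826	BCFA
C18319	K00166	BCFA
C18319	K00167	BCFA
C18319	K00826	BCFA
C18319	K00382	BCFA
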