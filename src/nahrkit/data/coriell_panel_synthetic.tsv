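population	individual	allele1	allele2
Coriell_CAU	CAU_001	A	B
Coriell_CAU	CAU_002	A	B
Coriell_CAU	CAU_003	A	B
Coriell_CAU	CAU_004	A	B
Coriell_CAU	CAU_005	A	B
Coriell_CAU	CAU_006	A	B
Coriell_CAU	CAU_007	A	B
Coriell_CAU	CAU_008	A	B
Coriell_CAU	CAU_009	A	B
Coriell_CAU	CAU_010	A	B
Coriell_CAU	CAU_011	A	B
Coriell_CAU	CAU_012	A	B
Coriell_CAU	CAU_013	A	B
Coriell_CAU	CAU_014	A	B
Coriell_CAU	CAU_015	A	B
Coriell_CAU	CAU_016	A	B
Coriell_CAU	CAU_017	A	B
Coriell_CAU	CAU_018	A	B
Coriell_CAU	CAU_019	A	B
Coriell_CAU	CAU_020	A	B
Coriell_CAU	CAU_021	A	B
Coriell_CAU	CAU_022	A	B
Coriell_CAU	CAU_023	A	B
Coriell_CAU	CAU_024	A	B
Coriell_CAU	CAU_025	A	B
Coriell_CAU	CAU_026	A	B
Coriell_CAU	CAU_027	A	B
Coriell_CAU	CAU_028	A	B
Coriell_CAU	CAU_029	A	B
Coriell_CAU	CAU_030	A	B
Coriell_CAU	CAU_031	A	B
Coriell_CAU	CAU_032	A	B
Coriell_CAU	CAU_033	A	B
Coriell_CAU	CAU_034	A	B
Coriell_CAU	CAU_035	A	B
Coriell_CAU	CAU_036	A	B
Coriell_CAU	CAU_037	A	B
Coriell_CAU	CAU_038	B	B
Coriell_CAU	CAU_039	B	B
Coriell_CAU	CAU_040	B	B
Coriell_CAU	CAU_041	B	B
Coriell_CAU	CAU_042	B	B
Coriell_CAU	CAU_043	B	B
Coriell_CAU	CAU_044	B	B
Coriell_CAU	CAU_045	B	B
Coriell_CAU	CAU_046	B	B
Coriell_CAU	CAU_047	B	B
Coriell_CAU	CAU_048	B	B
Coriell_CAU	CAU_049	B	B
Coriell_CAU	CAU_050	B	B
Coriell_CAU	CAU_051	B	B
Coriell_CAU	CAU_052	B	B
Coriell_CAU	CAU_053	B	B
Coriell_CAU	CAU_054	B	B
Coriell_CAU	CAU_055	B	B
Coriell_CAU	CAU_056	B	B
Coriell_CAU	CAU_057	B	B
Coriell_CAU	CAU_058	B	B
Coriell_CAU	CAU_059	B	B
Coriell_CAU	CAU_060	B	B
Coriell_CAU	CAU_061	B	B
Coriell_CAU	CAU_062	B	B
Coriell_CAU	CAU_063	B	B
Coriell_CAU	CAU_064	B	B
Coriell_CAU	CAU_065	B	B
Coriell_CAU	CAU_066	B	B
Coriell_CAU	CAU_067	B	B
Coriell_CAU	CAU_068	B	B
Coriell_CAU	CAU_069	B	B
Coriell_CAU	CAU_070	B	B
Coriell_CAU	CAU_071	B	B
Coriell_CAU	CAU_072	B	B
Coriell_CAU	CAU_073	B	B
Coriell_CAU	CAU_074	B	B
Coriell_CAU	CAU_075	B	B
Coriell_CAU	CAU_076	B	B
Coriell_CAU	CAU_077	B	B
Coriell_CAU	CAU_078	B	B
Coriell_CAU	CAU_079	B	B
Coriell_CAU	CAU_080	B	B
Coriell_CAU	CAU_081	B	B
Coriell_CAU	CAU_082	B	B
Coriell_CAU	CAU_083	B	B
Coriell_CAU	CAU_084	B	B
Coriell_CAU	CAU_085	B	B
Coriell_CAU	CAU_086	B	B
Coriell_CAU	CAU_087	B	B
Coriell_CAU	CAU_088	B	B
Coriell_CAU	CAU_089	B	B
Coriell_CAU	CAU_090	B	B
Coriell_CAU	CAU_091	B	B
Coriell_CAU	CAU_092	B	B
Coriell_CAU	CAU_093	B	B
Coriell_CAU	CAU_094	B	B
Coriell_CAU	CAU_095	B	B
Coriell_CAU	CAU_096	B	B
Coriell_CAU	CAU_097	B	B
Coriell_CAU	CAU_098	B	B
Coriell_CAU	CAU_099	B	B
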