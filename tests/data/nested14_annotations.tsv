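g001	GO:05
g002	GO:05
g003	GO:05
g004	GO:05
g005	GO:05
g006	GO:05
g007	GO:05
g008	GO:05
g009	GO:05
g010	GO:05
g011	GO:06
g012	GO:06
g013	GO:06
g014	GO:06
g015	GO:06
g016	GO:06
g017	GO:06
g018	GO:06
g019	GO:06
g020	GO:06
g021	GO:07
g022	GO:07
g023	GO:07
g024	GO:07
g025	GO:07
g026	GO:07
g027	GO:07
g028	GO:07
g029	GO:07
g030	GO:07
g031	GO:07
g032	GO:07
g033	GO:07
g034	GO:07
g035	GO:07
g036	GO:07
g037	GO:07
g038	GO:07
g039	GO:07
g040	GO:07
g041	GO:08
g042	GO:08
g043	GO:08
g044	GO:08
g045	GO:08
g046	GO:08
g047	GO:08
g048	GO:08
g049	GO:08
g050	GO:08
g051	GO:09
g052	GO:09
g053	GO:09
g054	GO:09
g055	GO:09
g056	GO:09
g057	GO:09
g058	GO:09
g059	GO:09
g060	GO:09
g061	GO:10
g062	GO:10
g063	GO:10
g064	GO:10
g065	GO:10
g066	GO:10
g067	GO:10
g068	GO:10
g069	GO:10
g070	GO:10
g071	GO:10
g071	GO:11
g072	GO:13
g073	GO:13
g074	GO:13
g075	GO:13
g076	GO:13
g077	GO:13
g078	GO:13
g079	GO:13
g080	GO:10
g080	GO:11
g081	GO:11
g081	GO:12
g082	GO:14
g083	GO:14
g084	GO:14
g085	GO:14
g086	GO:14
g087	GO:14
g088	GO:14
g089	GO:14
g090	GO:11
g090	GO:12
g091	GO:12
g092	GO:12
g093	GO:12
g094	GO:12
g095	GO:12
g096	GO:12
g097	GO:12
g098	GO:12
g099	GO:12
g100	GO:12
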