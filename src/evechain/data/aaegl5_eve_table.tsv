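identifier	event	virus	virus_start	virus_end	chromosome	host_start	host_end	length	virus_gap	mosquito_gap
AE1.1	1	MV	9954	10089	1	91833453	91833318	135
AE2.2	2	XAFV	2744	3050	2	461307129	461307435	306
AE3.2	2	XAFV	3409	3466	2	461307695	461307752	57	359	260
AE4.2	2	XAFV	3659	3801	2	461307924	461308066	142	193	172
AE5.2	2	XAFV	5188	6416	2	461309404	461310638	1234	1387	1338
AE6.2	2	XAFV	6823	6936	2	461311033	461311146	113	407	395
AE7.2	2	XAFV	7537	8296	2	461311735	461312495	760	601	589
AE8.2	2	XAFV	2269	3050	2	461318326	461319107	781
AE9.2	2	XAFV	3409	3587	2	461319367	461319524	157	359	260
AE10.2	2	XAFV	5456	6090	2	461335651	461336291	640
AE11.2	2	XAFV	5188	5619	2	461337125	461337562	437
AE12.2	2	XAFV	5456	5532	2	461338469	461338545	76
AE13.2	2	XAFV	5188	6086	2	461343230	461344110	880
AE14.2	2	XAFV	2438	3801	2	461350743	461352084	1341
AE15.2	2	XAFV	7758	7974	2	461357982	461358198	216	3957	5898
AE16.2	3	XAFV	8327	9766	2	469226073	469224634	1439
AE17.2	3	XAFV	9622	10083	2	469282615	469282163	452
AE18.3	4	XAFV	3537	3587	3	191321447	191321397	50
AE19.3	4	XAFV	2269	3242	3	191322900	191321928	972	295	481
AE20.3	4	XAFV	839	1677	3	191324077	191323249	828	592	349
AE21.3	4	XAFV	102	265	3	191324778	191324622	156	574	545
AE22.3	4	XAFV	3537	3587	3	191332002	191331952	50
AE23.3	4	XAFV	2269	3242	3	191333455	191332483	972	295	481
AE24.3	4	XAFV	839	1677	3	191334632	191333804	828	592	349
AE25.3	4	XAFV	102	265	3	191335333	191335177	156	574	545
AE26.4	5	XAFV	2729	3361	3	313469135	313469761	626
AE27.4	5	XAFV	2881	3044	3	313470472	313470635	163
AE28.4	5	XAFV	3080	3230	3	313471104	313471255	151
AE29.4	5	XAFV	2729	3361	3	313471984	313472610	626
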