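time	observable	mean	StdCol	n
0.0	Y1	0.4861148139700194	0.07621409591923299	5
1.0	Y1	0.5133400048986856	0.03581435368450581	5
2.0	Y1	0.5012520615663705	0.03539609922555224	5
3.0	Y1	0.4925942764587446	0.028792286246752594	5
5.0	Y1	0.5056837802042453	0.034576605614501224	5
7.0	Y1	0.4733381854680389	0.08530510167912528	5
10.0	Y1	0.5230378579679729	0.02028884014936509	5
14.0	Y1	0.49109349724971774	0.03728257255155129	5
17.0	Y1	0.4928952760214386	0.05738716666533864	5
21.0	Y1	0.5073916794319205	0.06625098976011562	5
0.0	Y2	0.5107345911416807	0.052216384889073035	5
1.0	Y2	0.5250923065345952	0.06133176930652822	5
2.0	Y2	0.5043476452028268	0.02206007749059771	5
3.0	Y2	0.4591496863621295	0.07029625790624168	5
5.0	Y2	0.518399263699905	0.042360938095650745	5
7.0	Y2	0.5189291078848872	0.06169920769906045	5
10.0	Y2	0.5023107631116062	0.0339407346361106	5
14.0	Y2	0.5006631109147834	0.042257555012007036	5
17.0	Y2	0.505942518358014	0.04577048554273749	5
21.0	Y2	0.48548289636425235	0.017704200417202918	5
0.0	Y3	0.6014819558590709	0.05951877288406355	5
1.0	Y3	0.6411579668393281	0.09033753228754812	5
2.0	Y3	0.6102707966772922	0.07926791013950299	5
3.0	Y3	0.656801620841509	0.06389242347789227	5
5.0	Y3	0.6898656337581388	0.04422616518834612	5
7.0	Y3	0.6784451991218197	0.025323754075949355	5
10.0	Y3	0.8452092065501986	0.06638367217059847	5
14.0	Y3	0.9093802459467619	0.10301397106457574	5
17.0	Y3	0.8702276623246703	0.07109908482886498	5
21.0	Y3	0.9678937920669528	0.09759993874817254	5
0.0	Y4	0.01907345623374504	0.0014433058481070763	5
1.0	Y4	0.02110208942143449	0.0009463548751062625	5
2.0	Y4	0.024308963447577304	0.0028851590117608293	5
3.0	Y4	0.03915818229760064	0.0020467294181181843	5
5.0	Y4	0.07054150238111528	0.006216415209611218	5
7.0	Y4	0.10099680267087477	0.013377690160210997	5
10.0	Y4	0.14069500832586782	0.011127797520660876	5
14.0	Y4	0.19111221586781862	0.025657018687899057	5
17.0	Y4	0.23114966221640962	0.014183035583097985	5
21.0	Y4	0.3065195800490913	0.04947946287041405	5
0.0	Y5	1.0265244415058021	0.09460848926109536	5
1.0	Y5	0.9515535571127733	0.137563522638594	5
2.0	Y5	1.021419420009752	0.0364912034216911	5
3.0	Y5	1.010588686037159	0.12193867020953772	5
5.0	Y5	1.0231533244154805	0.15599023891689437	5
7.0	Y5	0.9654161939071461	0.11243031515531685	5
10.0	Y5	1.06781529887983	0.14532849767683684	5
14.0	Y5	0.8601615766306725	0.10680897950187415	5
17.0	Y5	0.8867841012495908	0.08317766606701991	5
21.0	Y5	0.7742203784724986	0.08028592194679063	5
0.0	Y6	0.2884535576293068	0.020645177058601437	5
1.0	Y6	0.2996137149571364	0.03942625704229328	5
2.0	Y6	0.28367700396463336	0.024174418721452613	5
3.0	Y6	0.2680223163828176	0.012400188000732212	5
5.0	Y6	0.3110986654411734	0.02677170937822286	5
7.0	Y6	0.3193335317672856	0.0259374439499403	5
10.0	Y6	0.3051890643765326	0.048314145707873554	5
14.0	Y6	0.33362089595607314	0.032271808392774305	5
17.0	Y6	0.4200113050468399	0.04639981350857337	5
21.0	Y6	0.40013090784551303	0.04578389915418939	5
0.0	Y7	0.00458870948892313	0.0004238732286434306	5
1.0	Y7	0.5529160847536788	0.0598895849625974	5
2.0	Y7	0.47435459640373495	0.01797261061583529	5
3.0	Y7	0.390970402092239	0.06648071648435364	5
5.0	Y7	0.29648374583376613	0.028184857962833095	5
7.0	Y7	0.2541072336799311	0.023489668741043954	5
10.0	Y7	0.21830025996090302	0.021011471093469042	5
14.0	Y7	0.26903419312245813	0.01788337191616297	5
17.0	Y7	0.34750703342340133	0.05106607715957703	5
21.0	Y7	0.5913718489062993	0.03632170824759524	5
0.0	Y8	0.05119652316242439	0.0054441712554560845	5
1.0	Y8	0.05117803999673165	0.004701651617050525	5
2.0	Y8	0.0493746159990527	0.0019304938628533419	5
3.0	Y8	0.047014416139724687	0.008104968962981667	5
5.0	Y8	0.05254348724534447	0.004312834853046458	5
7.0	Y8	0.06310476607916324	0.005099909698284071	5
10.0	Y8	0.07434892902396732	0.005150882319169076	5
14.0	Y8	0.09631040418039731	0.00711878467692804	5
17.0	Y8	0.10154408094355638	0.00960700559249856	5
21.0	Y8	0.09590876064761822	0.010888225449823954	5
0.0	Y9	0.020086626794434632	0.002413002823828418	5
1.0	Y9	0.0834105823714871	0.007915356693047163	5
2.0	Y9	0.029420108447430232	0.004020354194804765	5
3.0	Y9	0.039254836095854666	0.004223520219962167	5
5.0	Y9	0.07072773097288783	0.0050115809224815676	5
7.0	Y9	0.11041975108592934	0.017268230814462774	5
10.0	Y9	0.14733056190550137	0.010967652890445656	5
14.0	Y9	0.19872291565092615	0.02069437527706034	5
17.0	Y9	0.22448828276447313	0.040346599120219276	5
21.0	Y9	0.2776088894048745	0.00969196456639514	5
0.0	Y10	0.01921358805533802	0.0023421463188634207	5
1.0	Y10	0.02036901707342666	0.0019657444483004486	5
2.0	Y10	0.031138147255292885	0.0014508949638712162	5
3.0	Y10	0.04397523498483262	0.003632193757681761	5
5.0	Y10	0.08717812143534397	0.011270963734009149	5
7.0	Y10	0.11125841228515587	0.007036440785089703	5
10.0	Y10	0.15860749125031798	0.006065440023648883	5
14.0	Y10	0.18516958509584677	0.010020562532413627	5
17.0	Y10	0.22936309003896288	0.020096528468912987	5
21.0	Y10	0.28972828718704924	0.03401776376842985	5
0.0	Y11	0.09958136953069924	0.00882357543642998	5
1.0	Y11	0.10247493740519283	0.006197802720830772	5
2.0	Y11	0.10187342886661872	0.007791555923856516	5
3.0	Y11	0.12184827235623012	0.013830600464057567	5
5.0	Y11	0.16756632440356953	0.01573881323854877	5
7.0	Y11	0.2545938127817493	0.023366197697041565	5
10.0	Y11	0.3345732286857478	0.03728443609124755	5
14.0	Y11	0.38139040111780426	0.02240356819064599	5
17.0	Y11	0.3760105729899649	0.023574627281924547	5
21.0	Y11	0.4354623453914227	0.03721373641356991	5
0.0	Y12	0.20376575200777522	0.02352036251633919	5
1.0	Y12	0.19440432448530456	0.010391960287869751	5
2.0	Y12	0.18837337363324588	0.013529016974845074	5
3.0	Y12	0.2175481841109616	0.013907802472294197	5
5.0	Y12	0.26517034318450894	0.016887753326188654	5
7.0	Y12	0.27604972696586944	0.020250456885992526	5
10.0	Y12	0.4040995952363427	0.014638766450362694	5
14.0	Y12	0.5451253208229785	0.06177721158198181	5
17.0	Y12	0.5408658367175472	0.05214320793046011	5
21.0	Y12	0.5843247610008916	0.09383149604153228	5
0.0	Y13	1.0747626401055002	0.10968700595074202	5
1.0	Y13	0.9841463158067938	0.05174657821745016	5
2.0	Y13	1.1865650738471445	0.1499235637507694	5
3.0	Y13	1.301169599276368	0.10223506239776209	5
5.0	Y13	1.547735044231374	0.22150026905445383	5
7.0	Y13	1.5847022156284325	0.235350959702308	5
10.0	Y13	1.4306186606198161	0.17714591398991023	5
14.0	Y13	1.4050925466086401	0.07998020438707225	5
17.0	Y13	1.6232734534371538	0.12492010842859184	5
21.0	Y13	1.7857660683629717	0.09686221785618787	5
0.0	Y14	0.9944894016211656	0.0549789923490739	5
1.0	Y14	1.0147547904259944	0.043956061940692785	5
2.0	Y14	0.950383851041327	0.11665570034370273	5
3.0	Y14	0.9565439526039521	0.09859454391028746	5
5.0	Y14	0.7111754849226035	0.08124600192495077	5
7.0	Y14	0.6543061620462921	0.05170226830654491	5
10.0	Y14	0.40175947448213306	0.03891644156813366	5
14.0	Y14	0.28165119564445595	0.03417978334180422	5
17.0	Y14	0.24372868978251866	0.008463244774151236	5
21.0	Y14	0.20138543394829606	0.012579833404893765	5
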