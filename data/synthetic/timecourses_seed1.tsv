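time	observable	mean	StdCol	n
0.0	Y1	0.5109983804681809	0.044578811801463204	5
1.0	Y1	0.511632605941619	0.022093120731285876	5
2.0	Y1	0.49315854185498254	0.02469611460113885	5
3.0	Y1	0.49493864815508	0.025433831487605325	5
5.0	Y1	0.491361475389337	0.07884783810317114	5
7.0	Y1	0.47311902556169094	0.042910145288158216	5
10.0	Y1	0.5263565348572976	0.07090630022041966	5
14.0	Y1	0.4845990313661477	0.04415873944220844	5
17.0	Y1	0.4664500793221037	0.025434016266535586	5
21.0	Y1	0.5053655114076966	0.02670576399375878	5
0.0	Y2	0.5061199096078263	0.037560104346065326	5
1.0	Y2	0.4817935700519905	0.04350004123103369	5
2.0	Y2	0.4807239667276084	0.033468419585219275	5
3.0	Y2	0.48786001163421905	0.04632909548576401	5
5.0	Y2	0.5180106425803576	0.04103510901056567	5
7.0	Y2	0.49951747316861794	0.04373165528124294	5
10.0	Y2	0.5019532747018631	0.05902803397711435	5
14.0	Y2	0.515943174580958	0.026652900015098333	5
17.0	Y2	0.5260264861270469	0.029487262086426994	5
21.0	Y2	0.4766782986682898	0.05637693652830445	5
0.0	Y3	0.623681367506666	0.0458724591733906	5
1.0	Y3	0.5988221361947235	0.07550437753408745	5
2.0	Y3	0.620818192447034	0.03466085205698601	5
3.0	Y3	0.631701565668904	0.047111414339654434	5
5.0	Y3	0.6916074399346398	0.14268642574282697	5
7.0	Y3	0.6884173164328911	0.05262520952031946	5
10.0	Y3	0.8160609646763104	0.03357846023842094	5
14.0	Y3	0.831502554716168	0.041995002515382344	5
17.0	Y3	0.924301937919159	0.08474243701629218	5
21.0	Y3	0.9050588610450596	0.05837118395155581	5
0.0	Y4	0.019158323315484827	0.001495403798675937	5
1.0	Y4	0.019954491291429104	0.0029397489496773505	5
2.0	Y4	0.026777766747425224	0.0016712336541838844	5
3.0	Y4	0.039753474520559294	0.003734602047080415	5
5.0	Y4	0.06869422773948859	0.005479474697235324	5
7.0	Y4	0.1062097700435765	0.010815905757212856	5
10.0	Y4	0.1545449346338975	0.02010830413221745	5
14.0	Y4	0.17694047005871133	0.014302174788728786	5
17.0	Y4	0.22299890226692046	0.03560324402819321	5
21.0	Y4	0.2976376929407042	0.03440859799201559	5
0.0	Y5	1.0496649051199172	0.14068241531891307	5
1.0	Y5	0.9862523095562581	0.12268966714613641	5
2.0	Y5	0.9783022401029824	0.04552893371815531	5
3.0	Y5	0.9578518873761362	0.04591272243508099	5
5.0	Y5	0.9841928756537882	0.05301474935025926	5
7.0	Y5	0.9283895256619102	0.07023549464928984	5
10.0	Y5	0.9467208532766815	0.1018051531149371	5
14.0	Y5	0.885378075607492	0.08588817087814103	5
17.0	Y5	0.8919705785893568	0.1078399194072347	5
21.0	Y5	0.805471428678761	0.07036034246135185	5
0.0	Y6	0.298671064587062	0.016347065512356772	5
1.0	Y6	0.29372162156844983	0.015108892654548536	5
2.0	Y6	0.2820788937036048	0.028058051241930126	5
3.0	Y6	0.2918713089891685	0.026465173296074812	5
5.0	Y6	0.30031929237260946	0.061640056949729835	5
7.0	Y6	0.30180030727945734	0.03310219466093746	5
10.0	Y6	0.3242321683880195	0.023394405884944368	5
14.0	Y6	0.34994985681624785	0.026401688041204005	5
17.0	Y6	0.39987434362505386	0.028557051603582465	5
21.0	Y6	0.4376683904385629	0.04176493125326864	5
0.0	Y7	0.00414378836183215	0.00014804513394703456	5
1.0	Y7	0.5657180272211981	0.03806676169517919	5
2.0	Y7	0.461094180608655	0.04214352310874318	5
3.0	Y7	0.38901138514038336	0.049571542522262126	5
5.0	Y7	0.2945791140739106	0.010214704973607054	5
7.0	Y7	0.24386559602867397	0.020069933565197817	5
10.0	Y7	0.23198128065190846	0.02141136456701592	5
14.0	Y7	0.26891222402852444	0.038162839088663796	5
17.0	Y7	0.3315408804415768	0.028320388970627164	5
21.0	Y7	0.54699270218759	0.03935176716200741	5
0.0	Y8	0.05044401272070752	0.005270030826776764	5
1.0	Y8	0.04950926246506984	0.0039069713654805585	5
2.0	Y8	0.050960940184598826	0.0033915136511197506	5
3.0	Y8	0.0522976040539487	0.0046885732142557465	5
5.0	Y8	0.05390915752472082	0.009053046283780453	5
7.0	Y8	0.062332578781799416	0.005784558287023084	5
10.0	Y8	0.07970275059488978	0.007231958112434709	5
14.0	Y8	0.09261890326745632	0.006695723925040163	5
17.0	Y8	0.09797452681418634	0.004854149776413968	5
21.0	Y8	0.0946284145472258	0.009581012105317662	5
0.0	Y9	0.019195330777009162	0.002848436073119166	5
1.0	Y9	0.09133624264915947	0.007467732924148663	5
2.0	Y9	0.027925611282580087	0.0034641594157110924	5
3.0	Y9	0.0423345634081599	0.003018134058464208	5
5.0	Y9	0.07481675265243473	0.002494964255149849	5
7.0	Y9	0.10850999292130707	0.006876613893514377	5
10.0	Y9	0.15457846027213346	0.014835441498323242	5
14.0	Y9	0.18245435466621318	0.014363143598694518	5
17.0	Y9	0.23944533310869504	0.02214867027682182	5
21.0	Y9	0.32548296284408884	0.030079496514113294	5
0.0	Y10	0.01976222746387068	0.0012991494239307459	5
1.0	Y10	0.023161308672611184	0.0019347845055073705	5
2.0	Y10	0.03313314659408653	0.00291820257058443	5
3.0	Y10	0.04521125710342645	0.0009726380312684646	5
5.0	Y10	0.07671227154557379	0.006604674993423223	5
7.0	Y10	0.11404204584308553	0.005832787110647165	5
10.0	Y10	0.16309372111062342	0.01582862924726443	5
14.0	Y10	0.19958213606462807	0.016887445442371727	5
17.0	Y10	0.2370302598409678	0.019282955550010302	5
21.0	Y10	0.3046102128761273	0.03344711675890418	5
0.0	Y11	0.09427892168325411	0.015413111271633289	5
1.0	Y11	0.10387246042626239	0.00757391799118695	5
2.0	Y11	0.10048292704973702	0.013046194568672195	5
3.0	Y11	0.12145172088748342	0.009239095997626194	5
5.0	Y11	0.1918523622689174	0.02612296654907838	5
7.0	Y11	0.24044124864812008	0.034036995665368934	5
10.0	Y11	0.3230144396914222	0.025222065332638946	5
14.0	Y11	0.3813705703325467	0.04193231021708414	5
17.0	Y11	0.3873180255937587	0.0294293676390892	5
21.0	Y11	0.4917834570162979	0.0443420882351796	5
0.0	Y12	0.18803430225273893	0.01884126908772344	5
1.0	Y12	0.21042625784394686	0.010905516028480219	5
2.0	Y12	0.20972967804151849	0.017773892737829824	5
3.0	Y12	0.21057387358540872	0.027470473398284272	5
5.0	Y12	0.2596219264971061	0.016746901332287293	5
7.0	Y12	0.2666107433264281	0.030012794165831646	5
10.0	Y12	0.41056936252049503	0.029281184093716443	5
14.0	Y12	0.49396054774315185	0.07224058622539557	5
17.0	Y12	0.5012152099896946	0.06492024537570706	5
21.0	Y12	0.5812341036463453	0.06325113264740596	5
0.0	Y13	1.048873577292938	0.09841230210145306	5
1.0	Y13	1.05458686331098	0.1278664782481937	5
2.0	Y13	1.1801338930099015	0.17600379810273029	5
3.0	Y13	1.3804374759470766	0.059025208303308256	5
5.0	Y13	1.495440223342385	0.16057160100054055	5
7.0	Y13	1.6563273082575214	0.2031786584993642	5
10.0	Y13	1.4784253027346161	0.20414648259051088	5
14.0	Y13	1.4642490296619388	0.09018573556530134	5
17.0	Y13	1.6178540311317295	0.10800843434790994	5
21.0	Y13	1.6115063018593492	0.2054660976492865	5
0.0	Y14	0.9514642503618786	0.044665148031822366	5
1.0	Y14	0.9405304330947152	0.12132773196876522	5
2.0	Y14	0.8529142256852023	0.10027710467238363	5
3.0	Y14	0.9438767582453981	0.07348595006331243	5
5.0	Y14	0.7207141414115432	0.09572323156242396	5
7.0	Y14	0.6197435024820358	0.0461547079898535	5
10.0	Y14	0.41079582837610634	0.04409485746513717	5
14.0	Y14	0.26259191205123933	0.044237677800808235	5
17.0	Y14	0.23881349222292636	0.021009370484609057	5
21.0	Y14	0.19340769846011857	0.01825842266643073	5
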