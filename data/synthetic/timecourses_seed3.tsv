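time	observable	mean	StdCol	n
0.0	Y1	0.488829340385584	0.08347629788149329	5
1.0	Y1	0.5000396944087422	0.0999383362865141	5
2.0	Y1	0.4798758241536049	0.023849419502987943	5
3.0	Y1	0.5080234121256085	0.02888156661229094	5
5.0	Y1	0.5123316205978101	0.039916357223771085	5
7.0	Y1	0.522653780484814	0.045592169388789454	5
10.0	Y1	0.4973181827345491	0.03461093124165183	5
14.0	Y1	0.4593397910646077	0.07994641287364222	5
17.0	Y1	0.4913501283454159	0.033953271721979705	5
21.0	Y1	0.5280681880917667	0.030180569242694702	5
0.0	Y2	0.4982034519499992	0.0318168700895882	5
1.0	Y2	0.4805354361937605	0.06558886905508612	5
2.0	Y2	0.4583390406688153	0.05773256773232892	5
3.0	Y2	0.4795350241287594	0.06568013885045068	5
5.0	Y2	0.5114319369566702	0.05379053583820658	5
7.0	Y2	0.49676273483569416	0.06065046364785013	5
10.0	Y2	0.5597850772230373	0.0257001588903402	5
14.0	Y2	0.48270519842394	0.0543733720572817	5
17.0	Y2	0.4935368642959034	0.03612028182232848	5
21.0	Y2	0.5166231187136506	0.05749716045186901	5
0.0	Y3	0.597064633545435	0.037141839819581836	5
1.0	Y3	0.643539400812714	0.06500831067425729	5
2.0	Y3	0.6190431425494038	0.0935218011693788	5
3.0	Y3	0.6290462293806642	0.09884758627921258	5
5.0	Y3	0.6950810924896115	0.08370923510879985	5
7.0	Y3	0.7797894133854747	0.05453243722369064	5
10.0	Y3	0.8309470248604107	0.09912633713686754	5
14.0	Y3	0.8833374205842819	0.05328731374520789	5
17.0	Y3	0.9323727603298249	0.1224740015090135	5
21.0	Y3	0.9046871623324753	0.0914032292614013	5
0.0	Y4	0.019441148034639387	0.0015139048894878425	5
1.0	Y4	0.019636197616975583	0.0007812626306521184	5
2.0	Y4	0.027190706852208674	0.0015438000264410556	5
3.0	Y4	0.03821836372214033	0.005468306950751588	5
5.0	Y4	0.07749639532200298	0.003721876300862979	5
7.0	Y4	0.10818284966154064	0.01154515858598513	5
10.0	Y4	0.15303733691279695	0.014814856854680362	5
14.0	Y4	0.19715192768469897	0.015639833797862452	5
17.0	Y4	0.21849386679528218	0.01842703155119744	5
21.0	Y4	0.30752497015378244	0.02532611356548916	5
0.0	Y5	1.0042811850149105	0.11648962421502267	5
1.0	Y5	1.0153670895185283	0.11445609682923129	5
2.0	Y5	0.9744671813746578	0.04561072255203318	5
3.0	Y5	0.9736349561610332	0.03333049960999382	5
5.0	Y5	0.9754348599564466	0.14673643706805292	5
7.0	Y5	0.9425229047632978	0.09939605670743074	5
10.0	Y5	0.9214673380684362	0.07123380368905556	5
14.0	Y5	0.8951045138873143	0.0880636257251694	5
17.0	Y5	0.8914196492479609	0.09309872043747214	5
21.0	Y5	0.8545651472088742	0.09793262213299139	5
0.0	Y6	0.3178035509554948	0.03197041328746324	5
1.0	Y6	0.30751069364969436	0.03225472185861554	5
2.0	Y6	0.2995695156335202	0.024642702115965785	5
3.0	Y6	0.3215754329769981	0.012840852450982107	5
5.0	Y6	0.31899895672431544	0.01583699480785917	5
7.0	Y6	0.3204328762088358	0.029009010635601542	5
10.0	Y6	0.33145055699235887	0.040982947240814124	5
14.0	Y6	0.3681980495058991	0.03316308904811796	5
17.0	Y6	0.39589666422808906	0.06213418831045928	5
21.0	Y6	0.40816344211428995	0.05042689567956105	5
0.0	Y7	0.00407531448331788	0.0003321422191709567	5
1.0	Y7	0.5281402117082494	0.060076710824211836	5
2.0	Y7	0.45897787806597157	0.05299740900926375	5
3.0	Y7	0.41631276945965423	0.01969431999648365	5
5.0	Y7	0.28283243665883184	0.01736817124673599	5
7.0	Y7	0.2597544874661494	0.04131980344483873	5
10.0	Y7	0.23112752347642318	0.0174623849527758	5
14.0	Y7	0.2549984153395924	0.04431381739814686	5
17.0	Y7	0.34705533062068233	0.047644311447023725	5
21.0	Y7	0.5640147516583334	0.03370726377925506	5
0.0	Y8	0.05355266993417682	0.0055779185299731394	5
1.0	Y8	0.049375471601446855	0.003216036911419545	5
2.0	Y8	0.04802726869147466	0.006866763054944505	5
3.0	Y8	0.048428671720000135	0.005537186092784415	5
5.0	Y8	0.054570406556008214	0.004043346608662823	5
7.0	Y8	0.06473620179152476	0.005606920368930871	5
10.0	Y8	0.07844373836711108	0.005632885873122282	5
14.0	Y8	0.09277168960934196	0.011506617934807926	5
17.0	Y8	0.09883292006005498	0.0046008044186792284	5
21.0	Y8	0.09676938632391285	0.008621735260222004	5
0.0	Y9	0.019877948592756794	0.002144341720127267	5
1.0	Y9	0.09786555556864782	0.00246000417754553	5
2.0	Y9	0.03188003798739837	0.0025408367447306646	5
3.0	Y9	0.04160797016830654	0.006244953779157793	5
5.0	Y9	0.07549033706976409	0.0039933693663522654	5
7.0	Y9	0.11261155698552441	0.006087215296262603	5
10.0	Y9	0.13983508012480209	0.014867336432967535	5
14.0	Y9	0.19002276271518403	0.014681426310585919	5
17.0	Y9	0.21397817981245137	0.027201883001782886	5
21.0	Y9	0.29947183129293165	0.014643035633209917	5
0.0	Y10	0.01972585575008336	0.0014241989767328103	5
1.0	Y10	0.023161389734740336	0.0015026636690502245	5
2.0	Y10	0.03163125913834743	0.002305991373135988	5
3.0	Y10	0.048844028424877395	0.00576421007030564	5
5.0	Y10	0.07446514127358227	0.008365533258843441	5
7.0	Y10	0.10710222522307884	0.010909119823832587	5
10.0	Y10	0.14955438727366208	0.01857167286841979	5
14.0	Y10	0.18785976950313338	0.009486844703630131	5
17.0	Y10	0.2581349812375443	0.013080535148125495	5
21.0	Y10	0.3325705874005672	0.03211435482354657	5
0.0	Y11	0.10528038026792799	0.006375185394974772	5
1.0	Y11	0.10331098174392155	0.008389413713084623	5
2.0	Y11	0.10958117936835046	0.009446310642889933	5
3.0	Y11	0.1167991766580893	0.008484978810332207	5
5.0	Y11	0.17522578762638671	0.009524014750409798	5
7.0	Y11	0.26944610994337637	0.012643662252999701	5
10.0	Y11	0.3250654335251531	0.015177816948419643	5
14.0	Y11	0.3696068444533021	0.04086378422993218	5
17.0	Y11	0.38743839459261703	0.04517243801032542	5
21.0	Y11	0.490444400988557	0.03348908753161173	5
0.0	Y12	0.19145737063882973	0.02200037425055653	5
1.0	Y12	0.20301860833384247	0.01587614011443754	5
2.0	Y12	0.18737987411411774	0.043153752344844996	5
3.0	Y12	0.21097540097539175	0.01680922893207405	5
5.0	Y12	0.24701895090457654	0.012573912824465811	5
7.0	Y12	0.31423589102213784	0.03968151141171696	5
10.0	Y12	0.4071785465877782	0.05517355561535668	5
14.0	Y12	0.530766919854399	0.06096873692701392	5
17.0	Y12	0.6113710895552569	0.025830893472699176	5
21.0	Y12	0.6027962186712517	0.04716720411892058	5
0.0	Y13	0.9746119606608712	0.0602351255933285	5
1.0	Y13	1.043412609931566	0.10287627308430501	5
2.0	Y13	1.2402760816572485	0.15754626370084623	5
3.0	Y13	1.40765353990173	0.16015309470712236	5
5.0	Y13	1.4188230472516719	0.1724932812801296	5
7.0	Y13	1.5182776311995891	0.08650820400641299	5
10.0	Y13	1.5439535557422395	0.1461987421874824	5
14.0	Y13	1.5356364276468537	0.14842334308307528	5
17.0	Y13	1.5403246611398584	0.14901623406964426	5
21.0	Y13	1.724138677874172	0.12823608789785468	5
0.0	Y14	0.9423179266562265	0.044930811848372006	5
1.0	Y14	1.0861052612417048	0.08577426899095032	5
2.0	Y14	0.864123545372164	0.08117145132704026	5
3.0	Y14	0.9223532105399134	0.09426235394190824	5
5.0	Y14	0.782291067282572	0.05350130045419999	5
7.0	Y14	0.6846029165479868	0.07902748726840735	5
10.0	Y14	0.41822821344704375	0.05355060544378766	5
14.0	Y14	0.2647434168755443	0.022625460848459164	5
17.0	Y14	0.23714528342101238	0.01921699930092936	5
21.0	Y14	0.20979411681012267	0.030216946875023992	5
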