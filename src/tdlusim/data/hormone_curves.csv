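day,f_pi,f_ai
0.0,0.3,1.0
0.25,0.28970296408009283,0.8932490456540554
0.5,0.2809025117944603,0.7888181565281899
0.75,0.2734840518302692,0.6891902934903561
1.0,0.26733299287468687,0.5968484174085065
1.25,0.26233474361488046,0.5142754891505934
1.5,0.2583747127380171,0.44395446958456963
1.75,0.2553383089312638,0.3883683195783877
2.0,0.25311094088178787,0.35
2.25,0.2515780172767564,0.3222633668535003
2.5,0.25062494680333647,0.29685404989559294
2.75,0.2501371381486953,0.27367767062314535
3.0,0.25,0.2526398505330256
3.25,0.2521513389742695,0.2336462111221013
3.5,0.25823120998850957,0.21660237388724032
3.75,0.267678394179867,0.20141396032531045
4.0,0.27993167268548913,0.18798659193317946
4.25,0.294429826642523,0.17622589020771512
4.5,0.3106116371881155,0.16603747664578522
4.75,0.32791588545941397,0.1573269727442576
5.0,0.3457813525935653,0.15
5.25,0.3636468197277166,0.1435962301587302
5.5,0.38095106799901507,0.1376984126984127
5.75,0.39713287854460766,0.13227678571428572
6.0,0.41163103250164146,0.1273015873015873
6.25,0.42388431100726354,0.12274305555555556
6.5,0.4333314951986211,0.11857142857142858
6.75,0.43941136621286103,0.11475694444444444
7.0,0.44156270518713064,0.11126984126984128
7.25,0.43991039037402113,0.10808035714285713
7.5,0.4352257687336186,0.10515873015873016
7.75,0.42791732446431197,0.1024751984126984
8.0,0.41839354176449006,0.1
8.25,0.40706290483254187,0.09760582010582011
8.5,0.3943338978668562,0.09521164021164022
8.75,0.380615005065822,0.09285714285714286
9.0,0.3663147106278282,0.0905820105820106
9.25,0.3518414987512637,0.08842592592592594
9.5,0.3376038536345174,0.08642857142857142
9.75,0.32401025947597817,0.08462962962962964
10.0,0.311469200474035,0.08306878306878307
10.25,0.3003891608270766,0.08178571428571428
10.5,0.2911786247334921,0.08082010582010582
10.75,0.2842460763916702,0.08021164021164022
11.0,0.28,0.08
11.25,0.2772817025851419,0.08
11.5,0.27467590877250264,0.08
11.75,0.27220622915859066,0.08
12.0,0.2698962743399144,0.08
12.25,0.2677696549129824,0.08
12.5,0.26584998147430283,0.08
12.75,0.26416086462038424,0.08
13.0,0.26272591494773506,0.08
13.25,0.2615687430528636,0.08
13.5,0.26071295953227835,0.08
13.75,0.2601821749824877,0.08
14.0,0.26,0.08
14.25,0.2608363393391148,0.08018427938808373
14.5,0.2632681668660287,0.08072061191626409
14.75,0.26717969684509574,0.08158423913043478
15.0,0.2724551435406699,0.08275040257648954
15.25,0.27897872121710526,0.08419434380032206
15.5,0.286634644138756,0.08589130434782609
15.75,0.2953071265699761,0.08781652576489533
16.0,0.30488038277511964,0.08994524959742352
16.25,0.31523862701854066,0.09225271739130435
16.5,0.3262660735645933,0.09471417069243156
16.75,0.3378469366776316,0.09730485104669888
17.0,0.3498654306220096,0.1
17.25,0.36220576966208134,0.10324690700773412
17.5,0.37475216806220096,0.1074845579013378
17.75,0.3873888400867225,0.11267573879076087
18.0,0.4,0.11878323578595318
18.25,0.4145731575624668,0.12576983499686456
18.5,0.43291301169590646,0.1335983225334448
18.75,0.4546295604066986,0.14223148450564382
19.0,0.4793328017012228,0.15163210702341137
19.25,0.5066327335858587,0.16176297619669733
19.5,0.5361393540669857,0.1725868781354515
19.75,0.5674626611509835,0.18406659894962377
20.0,0.6002126528442318,0.1961649247491639
20.25,0.63399932715311,0.20884464164402175
20.5,0.6684326820839979,0.22206853574414717
20.75,0.7031227156432749,0.23579939315948995
21.0,0.7376794258373205,0.25
21.25,0.7717128106725146,0.2668407423575835
21.5,0.8048328681552366,0.2881525535195936
21.75,0.836649596291866,0.31338904038915094
22.0,0.8667729930887826,0.3420038098693759
22.25,0.8948130565523656,0.37345046886338895
22.5,0.9203797846889954,0.4071826242743106
22.75,0.9430831755050504,0.4426538830052612
23.0,0.962533227006911,0.4793178519593614
23.25,0.978339937200957,0.5166281380397315
23.5,0.9901133040935672,0.554038348149492
23.75,0.9974633256911216,0.5910020891917634
24.0,1.0,0.6269729680696662
24.25,0.9963134765625,0.6614045916863208
24.5,0.9855078125,0.6937505669448476
24.75,0.9679638671875,0.723464500748367
25.0,0.9440624999999999,0.75
25.25,0.9141845703125,0.7744773338449636
25.5,0.8787109375,0.7983662149346111
25.75,0.8380224609375,0.8216444154312669
26.0,0.7925,0.8442897074972547
26.25,0.7425244140625,0.8662798632948987
26.5,0.6884765625,0.887592654986523
26.75,0.6307373046875,0.9082058547344515
27.0,0.5696875,0.9280972347010084
27.25,0.5057080078125,0.9472445670485176
27.5,0.4391796875,0.9656256239393033
27.75,0.3704833984375,0.9832181775356893
28.0,0.30000000000000004,1.0
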