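"","thick_000","thick_001","thick_002","thick_003","thick_004","thick_005","thick_006","thick_007"
"site00_subj0000",2.6489681284,2.0866092542,2.3980893486,1.4467931184,3.2125406387,2.1290113635,3.2176556041,1.477138183
"site00_subj0001",1.8229832567,1.0759432587,2.7444533408,1.367677292,3.2968689931,1.9995074621,2.3732189466,1.3842496751
"site00_subj0002",1.9812434697,1.7280615352,2.4678566511,1.3207116053,3.008165656,1.9926421735,2.8269794168,1.2490144465
"site00_subj0003",2.1444944738,1.3683591516,2.1977432014,1.5138640059,3.0667585595,2.2980587,2.9845430416,1.5402014426
"site00_subj0004",2.2119790864,1.3503242024,2.4128302973,1.7774581689,2.839705615,2.2485805226,3.1184535562,1.5433807905
"site00_subj0005",2.361055209,1.6236990529,2.4434005424,1.7231768244,3.414539774,2.1794211673,3.1790521503,1.5180512015
"site00_subj0006",2.5201897523,1.8181024144,2.9271788818,1.5495063734,3.4753460433,2.1317743725,3.283073706,1.3795547686
"site00_subj0007",2.7070875029,1.3632006741,2.302645716,1.5202153899,3.3192618056,2.4229541973,3.1139170508,1.564349664
"site00_subj0008",2.5494259094,1.3819517443,2.4807164626,2.3300625573,3.6336536408,2.623530819,2.9933763554,2.2109905047
"site00_subj0009",2.0738400201,1.5468679321,2.6759364584,1.5908986987,3.0294943736,2.1997154733,2.7944294757,1.5212977057
"site00_subj0010",2.1655237601,1.0510951986,2.4630454878,1.4353891711,3.3912984836,1.9207288856,2.8906319972,1.6436457194
"site00_subj0011",2.2796032937,1.618926405,2.1130283717,1.2526838619,3.5585416695,1.897910627,2.8854504537,1.7734277622
"site00_subj0012",2.669834736,1.2618959059,2.6328569029,1.6807954547,3.468337039,2.4200350444,3.1654020902,2.0969394449
"site00_subj0013",2.2387147119,1.8450028783,2.6045637157,2.0558346611,3.307252959,2.1136948676,2.7976963764,1.0069277449
"site00_subj0014",2.4081949149,1.5787448008,2.9184340708,1.7255286578,3.4028458031,2.4432743663,2.4785582548,1.369623295
"site00_subj0015",2.1865165703,1.2908045869,2.3665330815,1.5153008463,3.396530374,2.1472133659,2.980319165,2.1978862678
"site00_subj0016",2.9222959912,1.9050182956,2.4903457983,1.4079725382,3.2053025541,2.232942917,3.1373165117,1.2769053067
"site00_subj0017",1.9514490429,1.631613866,2.3517721033,1.4664240053,3.0606128337,2.3312496886,3.081362194,1.2560857851
"site00_subj0018",2.413519246,1.6740529058,2.5102897762,1.8462737309,3.2865827892,2.5954628411,3.0845331989,1.4146906417
"site00_subj0019",2.0180230036,1.5562310246,2.4809810569,1.7390576324,3.3428005987,2.3853568215,3.3113031584,1.1894026421
"site01_subj0000",2.4651332998,1.5040028292,2.4272696069,2.2720680118,2.9821841196,2.4981875038,2.7009401957,1.6795106201
"site01_subj0001",2.5892666195,1.3793477915,2.8353097854,1.3186701345,3.0519585434,2.2853223865,2.8529449173,1.2589763675
"site01_subj0002",2.5893789645,1.3699651904,2.5657868247,1.7221859926,3.4816034985,2.5206521297,2.4349163256,1.72673453
"site01_subj0003",2.2944525523,1.5079293571,2.3408018743,1.2697336738,3.6817270521,2.0567952164,2.9951402175,1.0967012892
"site01_subj0004",2.3551698876,1.8118724539,2.7736590675,1.5903990091,3.2728854333,2.4601256185,2.6835578963,1.323407808
"site01_subj0005",2.3096439762,1.559538631,2.5780109704,1.755866188,3.3026737254,1.7727180307,2.9415520503,1.654536858
"site01_subj0006",2.8705247751,1.6118774516,2.7582789868,1.7351288364,3.4169307514,2.2568259441,2.5815841759,1.2678577721
"site01_subj0007",2.2955706427,1.4629746353,2.6671129988,2.1623827524,3.3733693243,2.1536234174,2.7802814199,1.0314414573
"site01_subj0008",2.1451274363,1.7968218439,2.5856180423,1.4160634382,3.2640133808,1.9327621291,3.1622735888,1.5617571988
"site01_subj0009",2.0764434935,1.6427308498,2.2852787373,1.4465466313,3.1996564647,2.4398128708,3.3615421046,1.9849243
"site01_subj0010",1.8808893454,0.9839313515,2.5474675374,1.7167876122,3.4356614787,2.1694182378,2.9957385546,1.8223034867
"site01_subj0011",2.2762184434,1.2658108613,2.5052417854,1.2455799844,3.4121151762,2.1937907342,2.8895801579,1.5436853916
"site01_subj0012",2.0357179376,1.5641134854,2.6085204412,1.426099932,3.1863982986,2.2819631333,3.0387126069,1.4548670194
"site01_subj0013",2.3203107298,1.7242106193,2.8239013554,1.5964239229,3.2369882222,2.3748868566,2.9258122888,1.846758973
"site01_subj0014",2.0615180401,1.2961540541,2.6180281213,1.2379175711,3.563790456,1.9661410136,3.1894821168,1.7451926382
"site01_subj0015",2.0435721244,1.46428757,2.5422478389,1.6698396365,3.0712462088,2.2063403803,2.9806464919,1.7314006487
"site01_subj0016",2.0419760514,1.857308088,2.4469141925,1.8402062646,3.352334219,2.3037417292,3.2892784719,1.7589452719
"site01_subj0017",2.4630577784,1.6477582121,2.4552553618,1.5028241286,3.2398799847,2.2187552966,2.4738589466,1.3242946318
"site01_subj0018",2.5622498167,1.7324095286,2.8014983924,1.6183171306,3.3041029079,2.6468397884,3.5617115351,1.3413383391
"site01_subj0019",2.3883366871,1.4102069481,2.347607827,1.5510339238,3.4265140294,2.4381219864,2.961563726,1.5006008067
"site02_subj0000",2.412068906,1.8351066376,2.5490742336,1.5441181886,3.2795232985,2.0353955845,2.6974079039,1.6119696365
"site02_subj0001",2.1806742926,1.6513697306,2.6536440469,1.672326676,3.4812370858,2.4729408408,2.7925880704,1.6613873497
"site02_subj0002",2.3784853544,1.9876510559,2.6091165338,1.8222098076,3.574917337,2.1374999028,3.2299092521,1.770515522
"site02_subj0003",2.455041156,1.63572536,2.3824833679,1.4619978744,3.3231816119,2.314072239,2.6352958008,1.2077072678
"site02_subj0004",2.3191316262,1.0094602103,2.6396759874,1.5516035058,3.5485876902,2.4179438136,3.0269775621,1.7978091297
"site02_subj0005",2.5846556846,1.3742284084,2.5253821467,1.203291752,3.0839241798,2.5802900839,3.2023219577,1.9231515453
"site02_subj0006",2.3286799807,1.7535327293,2.6129078486,2.1453380419,3.4025389174,2.5613114228,3.0213330853,1.2927956543
"site02_subj0007",2.3713581656,1.6246743471,2.3014713786,1.6005718372,3.2404484578,1.9947246682,3.7040473563,1.6057988742
"site02_subj0008",2.3497743477,1.6273279208,2.4983488669,1.5124912358,3.4523355601,2.4046724837,2.8955479849,1.9033650549
"site02_subj0009",2.4914542056,1.2245239762,2.5551201818,1.855884213,3.1081321416,2.0687143827,2.5301992053,1.1777492429
"site02_subj0010",2.1578459795,1.6223414373,2.1667972193,1.5310038817,3.3798610412,2.4749959884,2.6369813687,1.6942104673
"site02_subj0011",2.5594116982,1.7781827859,2.8225153775,2.2045198747,3.4506932182,2.3425759669,3.2541416388,1.5165295253
"site02_subj0012",2.5070582107,1.6684564984,2.7247138782,1.8301894082,3.3324936345,2.3565458631,2.4684640993,1.7175674847
"site02_subj0013",2.8307994608,1.6131573613,2.7307716344,1.733287434,3.5928739266,1.9130370073,3.2485762413,2.2043232539
"site02_subj0014",2.5554341457,1.656404115,2.5910000508,1.8003554583,3.4626070732,2.1367569247,2.8544217972,1.8954713751
"site02_subj0015",2.1914334837,1.5742223882,2.2886153736,1.7653841396,3.5785900625,2.0300364391,2.8471557814,1.3051950332
"site02_subj0016",1.8943128532,1.587270304,2.877411467,1.8445486926,3.3709407124,1.98757763,2.6227527412,1.6537458252
"site02_subj0017",2.277612391,1.6099806063,2.7407966359,1.582411702,3.3204447008,2.4402931401,3.4372963761,1.2296522038
"site02_subj0018",2.4552189764,2.2159061736,2.4881615372,1.732135569,2.952125358,1.7954944933,3.3488204054,1.9562768381
"site02_subj0019",2.4020189265,1.5194246159,2.3553162527,1.3267438166,3.0175307148,2.1944736728,2.5409661119,1.5651633346
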