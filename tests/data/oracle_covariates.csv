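subject_id,site,dx,age,sex
site00_subj0000,site00,0,23.936318195167527,0
site00_subj0001,site00,0,70.81876448086533,0
site00_subj0002,site00,1,47.98885869924591,0
site00_subj0003,site00,1,53.51264385642283,0
site00_subj0004,site00,0,51.57796019405845,1
site00_subj0005,site00,0,28.150804489266612,0
site00_subj0006,site00,1,28.569061705819117,1
site00_subj0007,site00,0,31.66818319615804,0
site00_subj0008,site00,1,22.793394837471148,1
site00_subj0009,site00,1,57.570770616604435,0
site00_subj0010,site00,1,46.61141258099224,1
site00_subj0011,site00,0,34.88108686816607,0
site00_subj0012,site00,1,22.327416032283917,1
site00_subj0013,site00,1,34.134341243497765,1
site00_subj0014,site00,1,43.98729001831217,1
site00_subj0015,site00,1,47.12048054487085,1
site00_subj0016,site00,0,28.401801285869404,0
site00_subj0017,site00,0,50.21621773500533,0
site00_subj0018,site00,1,23.001961805891227,0
site00_subj0019,site00,0,31.35780981613429,1
site01_subj0000,site01,1,24.388315303639267,0
site01_subj0001,site01,1,40.39218808845297,1
site01_subj0002,site01,0,36.46111134722876,1
site01_subj0003,site01,1,48.60955613741933,1
site01_subj0004,site01,0,50.84670271910987,1
site01_subj0005,site01,0,40.11989110595429,0
site01_subj0006,site01,1,43.13115192116362,1
site01_subj0007,site01,0,38.297749922125334,1
site01_subj0008,site01,0,23.439131785638423,1
site01_subj0009,site01,0,43.486075421821084,0
site01_subj0010,site01,1,52.260452493928284,0
site01_subj0011,site01,0,27.382205901059677,0
site01_subj0012,site01,0,46.13697974510196,1
site01_subj0013,site01,0,26.752383556858767,1
site01_subj0014,site01,1,39.41520304626639,1
site01_subj0015,site01,0,42.747921519574916,0
site01_subj0016,site01,1,42.12501998867643,1
site01_subj0017,site01,0,35.13133148412361,1
site01_subj0018,site01,1,37.472676126459405,1
site01_subj0019,site01,0,15.662299370144812,1
site02_subj0000,site02,0,41.47743861789035,1
site02_subj0001,site02,1,39.884606880255426,1
site02_subj0002,site02,0,12.167900970139659,1
site02_subj0003,site02,0,18.777416871473044,0
site02_subj0004,site02,1,36.44437038368496,1
site02_subj0005,site02,0,42.40954835142047,1
site02_subj0006,site02,0,15.730306223478978,1
site02_subj0007,site02,1,41.296761293410334,1
site02_subj0008,site02,0,8.800411344569326,1
site02_subj0009,site02,0,38.69851018522617,0
site02_subj0010,site02,0,20.345724897162803,0
site02_subj0011,site02,1,41.9032802170114,1
site02_subj0012,site02,0,32.398710556784266,1
site02_subj0013,site02,1,14.393622737465865,0
site02_subj0014,site02,0,17.82206834391363,1
site02_subj0015,site02,0,35.031079192015795,1
site02_subj0016,site02,1,30.296892737908088,1
site02_subj0017,site02,1,46.91012763599274,1
site02_subj0018,site02,0,21.81303415106337,1
site02_subj0019,site02,1,47.58045090661959,1
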