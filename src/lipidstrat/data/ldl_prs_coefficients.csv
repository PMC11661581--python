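rsid,effect_allele,effect_allele_freq,beta
rs77001,T,0.185,-0.0364
rs77002,T,0.51,0.0543
rs77003,G,0.196,-0.0302
rs77004,G,0.605,-0.0115
rs77005,A,0.225,0.0564
rs77006,A,0.423,-0.005
rs77007,A,0.776,0.0629
rs77008,G,0.41,0.0856
rs77009,T,0.264,-0.016
rs77010,T,0.165,0.0715
rs77011,T,0.757,0.0601
rs77012,A,0.155,-0.0507
rs77013,C,0.664,-0.0475
rs77014,C,0.493,-0.0265
rs77015,C,0.366,-0.0344
rs77016,G,0.119,-0.0272
rs77017,A,0.316,-0.0564
rs77018,T,0.492,-0.0461
rs77019,G,0.203,0.0049
rs77020,T,0.214,-0.0009
rs77021,T,0.088,-0.0324
rs77022,G,0.288,-0.027
rs77023,T,0.93,0.0391
rs77024,T,0.509,0.0362
rs77025,C,0.444,-0.042
rs77026,A,0.108,0.018
rs77027,A,0.822,-0.0151
rs77028,T,0.823,0.0928
rs77029,C,0.931,-0.0565
rs77030,C,0.815,-0.0513
rs77031,T,0.93,0.0027
rs77032,G,0.257,-0.0619
rs77033,G,0.772,0.0966
rs77034,A,0.657,-0.0852
rs77035,T,0.905,0.0683
rs77036,G,0.949,-0.0322
rs77037,T,0.434,-0.0554
rs77038,C,0.898,0.0936
rs77039,C,0.339,-0.0447
rs77040,T,0.268,-0.0696
rs77041,G,0.407,-0.0979
rs77042,G,0.324,0.0335
rs77043,C,0.706,0.0206
rs77044,T,0.606,0.0275
rs77045,C,0.469,0.0003
rs77046,G,0.696,0.0011
rs77047,A,0.925,-0.0804
rs77048,G,0.071,-0.1233
rs77049,T,0.271,0.0465
rs77050,G,0.921,-0.0269
rs77051,A,0.569,0.0222
rs77052,G,0.643,-0.0181
rs77053,T,0.696,0.0363
rs77054,C,0.568,-0.0496
rs77055,A,0.608,0.0527
rs77056,G,0.462,0.0372
rs77057,C,0.666,0.0957
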