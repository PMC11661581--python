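rsid,effect_allele,effect_allele_freq,beta
rs88001,A,0.236,-0.0213
rs88002,G,0.309,0.0207
rs88003,G,0.535,-0.0386
rs88004,A,0.144,-0.0454
rs88005,T,0.208,0.056
rs88006,T,0.655,-0.0587
rs88007,C,0.799,-0.0147
rs88008,A,0.533,0.0292
rs88009,A,0.413,0.0428
rs88010,G,0.078,0.0022
rs88011,G,0.721,-0.0263
rs88012,T,0.858,0.0587
rs88013,T,0.722,-0.0174
rs88014,G,0.44,-0.0205
rs88015,G,0.091,0.0247
rs88016,C,0.82,0.0387
rs88017,C,0.369,0.0704
rs88018,T,0.627,0.0037
rs88019,C,0.639,-0.0043
rs88020,G,0.939,0.0779
rs88021,T,0.833,0.0662
rs88022,A,0.14,0.0202
rs88023,A,0.849,0.0375
rs88024,C,0.551,-0.0124
rs88025,C,0.225,0.0214
rs88026,G,0.913,0.0251
rs88027,C,0.326,0.0359
rs88028,G,0.148,0.0001
rs88029,A,0.665,-0.0113
rs88030,C,0.161,-0.0028
rs88031,A,0.146,-0.0218
rs88032,G,0.477,-0.0575
rs88033,T,0.714,-0.0165
rs88034,G,0.862,-0.0039
rs88035,A,0.122,-0.0252
rs88036,G,0.681,-0.0276
rs88037,T,0.6,0.0196
rs88038,T,0.191,0.0077
rs88039,G,0.907,-0.0143
rs88040,G,0.751,-0.0472
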