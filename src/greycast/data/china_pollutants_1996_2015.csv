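Year,GDP,WDPC,SO2,Dust
1996,5539.01,32.2193,0.0161,0.0062
1997,6375.74,33.6343,0.0164,0.0103
1998,6921.71,32.4432,0.0168,0.0117
1999,7319.62,32.5936,0.0148,0.0092
2000,7778.40,32.7592,0.0157,0.0092
2001,8545.59,33.9270,0.0153,0.0084
2002,9449.23,34.2148,0.0150,0.0079
2003,10399.56,35.5421,0.0167,0.0081
2004,11679.27,37.1111,0.0173,0.0085
2005,13823.11,40.1511,0.0195,0.0090
2006,16106.53,40.8527,0.0197,0.0083
2007,19014.37,42.1558,0.0187,0.0075
2008,22370.96,43.0716,0.0175,0.0068
2009,26267.77,44.1439,0.0166,0.0064
2010,28870.42,46.0359,0.0163,0.0062
2011,33654.84,48.9251,0.0165,0.0095
2012,39060.42,50.5717,0.0156,0.0091
2013,42887.50,51.1085,0.0150,0.0094
2014,46833.94,52.3589,0.0144,0.0127
2015,50223.99,53.4928,0.0135,0.0112
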