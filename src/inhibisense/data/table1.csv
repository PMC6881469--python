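e_coli,m_capsulatus,s_oneidensis,code,pollutant,level_uM,actual_uM,confidence
0.09417,0.58032,0.06211,000010,Hg2+,1,0.66,high
0.46138,1.48214,1.08641,000011,Hg2+,10,1.3,low
1.19823,1.37532,1.65302,000100,Hg2+,100,66,high
0.09023,0.45121,0.67656,000111,Pb2+,1,1.25,high
0.48352,1.56176,0.87403,001000,Pb2+,10,22,high
1.21501,1.71608,2.47263,001001,Pb2+,100,83,high
0.54321,0.59745,1.31435,001100,Cd2+,1,1.37,high
0.76232,1.13421,1.54623,001101,Cd2+,10,26,high
1.55412,1.66534,1.82152,001110,Cd2+,100,76,high
0.55657,1.01232,0.01566,010001,atrazine,1,1.45,high
0.30508,2.09684,0.08508,010010,atrazine,10,24,high
1.06593,2.95676,0.97593,010011,atrazine,100,71,high
0.76231,1.20342,0.18784,010110,simazine,1,1.61,high
1.54231,2.47652,0.36941,010111,simazine,10,12.5,high
2.14325,2.89732,0.89876,011000,simazine,100,87,high
0.50453,1.13423,0.05566,011011,DDVP,1,1.1,high
1.65483,2.08563,0.02508,011100,DDVP,10,13.8,high
2.26314,2.87342,0.09593,011101,DDVP,100,99,high
0.03290,1.24231,0.49265,100000,hexane,1,1.2,high
1.04398,2.72134,0.56021,100001,hexane,10,32,high
2.89296,2.36532,0.75134,100010,hexane,100,83,high
0.02965,1.29912,0.27365,100101,octane,1,1.22,low
0.95120,2.61860,0.41931,100110,octane,10,17,high
2.00623,2.92861,0.65108,100111,octane,100,77,high
0.71525,1.47123,0.51132,101010,pentane,1,1.6,high
1.29723,2.68243,0.74167,101011,pentane,10,18,high
2.26211,2.85412,0.97133,101100,pentane,100,89,low
0.90123,2.51252,0.46326,101111,toluene,1,1.2,high
2.03251,2.85421,0.59131,110000,toluene,10,11,high
1.98589,2.85862,2.87109,110001,toluene,100,93,high
0.80173,1.01099,0.38134,110100,pyrene,1,1.4,high
2.01351,1.13209,0.53965,110101,pyrene,10,11.6,high
2.90598,1.07213,1.43312,110110,pyrene,100,83,high
0.15432,0.51974,0.63144,111001,ethanol,1,1.5,high
0.48453,1.53342,0.54762,111010,ethanol,10,12.1,high
1.31541,1.81653,2.65021,111011,ethanol,100,97,high
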