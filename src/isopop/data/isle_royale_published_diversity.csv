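period,locus,n,Na,Ho,He,Fis
1960-65,MAF46,51,4,0.55,0.53,0.05
1960-65,MAF70,51,4,0.73,0.66,0.00
1960-65,BM757,51,5,0.42,0.45,0.14
1960-65,BM848,51,4,0.57,0.61,0.17
1960-65,BM4513,51,3,0.71,0.48,-0.38
1960-65,McM58,51,5,0.83,0.68,-0.10
1960-65,RT5,51,3,0.06,0.06,-0.53
1960-65,RT9,51,4,0.51,0.58,0.15
1960-65,RT30,51,3,0.35,0.33,0.20
1970-75,MAF46,55,3,0.60,0.54,-0.11
1970-75,MAF70,55,4,0.71,0.67,-0.04
1970-75,BM757,55,5,0.72,0.70,-0.02
1970-75,BM848,55,4,0.46,0.56,0.18
1970-75,BM4513,55,3,0.44,0.42,-0.04
1970-75,McM58,55,5,0.81,0.64,-0.27
1970-75,RT5,55,3,0.07,0.06,-0.02
1970-75,RT9,55,5,0.60,0.60,0.02
1970-75,RT30,55,2,0.15,0.12,-0.07
1980-85,MAF46,50,2,0.60,0.50,-0.18
1980-85,MAF70,50,3,0.66,0.62,-0.08
1980-85,BM757,50,5,0.56,0.62,0.11
1980-85,BM848,50,4,0.55,0.57,0.03
1980-85,BM4513,50,5,0.67,0.56,-0.20
1980-85,McM58,50,5,0.61,0.66,0.08
1980-85,RT5,50,1,0.00,0.00,
1980-85,RT9,50,4,0.55,0.56,0.04
1980-85,RT30,50,2,0.20,0.25,0.20
1990-95,MAF46,50,3,0.61,0.51,-0.19
1990-95,MAF70,50,6,0.60,0.63,0.08
1990-95,BM757,50,5,0.60,0.67,0.12
1990-95,BM848,50,4,0.44,0.51,0.17
1990-95,BM4513,50,6,0.67,0.59,-0.13
1990-95,McM58,50,5,0.65,0.59,-0.08
1990-95,RT5,50,1,0.00,0.00,
1990-95,RT9,50,4,0.71,0.67,-0.05
1990-95,RT30,50,3,0.27,0.24,-0.10
2000-05,MAF46,45,2,0.33,0.50,0.34
2000-05,MAF70,45,5,0.71,0.67,-0.04
2000-05,BM757,45,6,0.64,0.68,0.07
2000-05,BM848,45,4,0.39,0.54,0.28
2000-05,BM4513,45,5,0.54,0.53,0.01
2000-05,McM58,45,5,0.73,0.65,-0.12
2000-05,RT5,45,3,0.05,0.05,-0.01
2000-05,RT9,45,4,0.64,0.56,-0.13
2000-05,RT30,45,3,0.20,0.18,-0.08
1960-65,Average,51,3.88,0.53,0.49,0.08
1970-75,Average,55,3.78,0.51,0.48,0.13
1980-85,Average,50,3.44,0.49,0.48,0.18
1990-95,Average,50,4.11,0.51,0.49,0.13
2000-05,Average,45,4.11,0.47,0.48,0.16
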