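River,NH3-N,TP,TN,COD_Mn,BOD5,COD_Cr,Fluoride
Daicun River,0.13,0.15,4.58,2.85,1.50,11.00,0.75
Dongda River,0.33,0.16,4.47,3.46,2.61,13.05,0.39
Fucheng River,1.74,0.40,4.33,4.55,4.58,14.82,0.50
Ge River,0.15,0.04,0.68,2.20,2.83,12.01,0.28
Jianshan River,0.11,0.07,0.76,2.73,2.18,8.73,0.36
Liangwang River,0.13,0.09,3.57,2.18,2.25,11.03,0.20
Lujv River,1.02,0.24,9.55,4.97,5.00,17.43,0.34
Niumo River,0.78,0.09,6.99,4.40,2.75,16.05,0.45
Shanchong River,0.23,0.13,2.32,3.25,3.10,13.10,0.47
Dajie River,4.89,1.44,8.28,8.98,15.49,47.50,0.56
Dalongtan River,0.67,0.13,2.41,3.45,3.43,15.92,0.18
Dazhuang River,3.64,0.48,7.71,4.78,8.37,28.58,0.39
Dongxida River,2.27,0.61,10.01,4.23,5.77,21.75,0.36
Luosipu River,1.67,0.55,13.13,3.26,4.23,19.42,0.65
Xue River,1.03,0.24,3.58,2.71,3.51,15.17,0.24
Yucun River,2.25,0.29,4.42,8.24,7.17,38.73,0.50
Zhoudeying River,0.59,0.23,1.36,2.51,3.23,14.75,0.25
Hongqi River,0.98,1.01,9.69,8.94,8.25,42.00,0.93
Zhong River,3.59,0.80,10.52,9.84,12.67,43.25,0.75
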