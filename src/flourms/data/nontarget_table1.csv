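printed_mz,printed_rt,vip,formula,analyte,compound_class,finder_score,reference,consistency
109.0292,3.32,1.70990591,C_6_H_5_O_2_,,,99,,inconsistent
123.0449,3.61,3.88331912,C_7_H_8_O_2_,,,99.9,,consistent
153.0191,3.32,1.24806817,C_7_H_6_O_4_,"2,4-dihydroxybenzoic acid",Phenolic acid,91.2,BS003106,consistent
153.0554,3.61,4.87762151,C_8_H_10_O_3_,,,94.6,,consistent
171.1023,7.77,1.32240845,C_8_H_14_O,,,90,,inconsistent
187.0966,7.65,2.20468526,C_9_H_16_O_4_,,,82.76,,inconsistent
199.0611,4.37,1.10983312,C_8_H_10_O_3_,Halleridone,Terpenoid,90.7,,inconsistent
215.0556,4.16,2.44049438,C_9_H_12_O_6_,,,90.8,,consistent
215.0914,6.36,1.91315487,C_11_H_20_S_2_,,,90.4,,inconsistent
223.0612,5.43,2.02782415,C_12_H_16_S_2_,,,89,,consistent
229.0717,4.57,1.35870769,C_10_H_14_O_6_,Elenaic acid,Lipid,85.1,literature,consistent
241.1186,5.76,2.91752206,C_11_H_14_O_6_,Elenaic acid derivative,Lipid,84.1,,inconsistent
253.2153,13.65,1.68171724,C_16_H_32_O_3_,16-Hydroxy-hexadecanoic acid,Lipid,91.1,PR100487,inconsistent
265.0753,7.30,1.11639129,C_10_H_18_O_6_S,,,90.5,,consistent
265.1462,13.56,5.82308316,C_12_H_26_O_4_S,,,90.9,,inconsistent
266.1507,13.64,1.01144158,C_6_H_21_N_9_OS,,,91.2,,consistent
267.1956,12.45,1.32783509,C_16_H_30_O_4_,Hexadecanedioate,Lipid derivative,86.3,JP001078,inconsistent
269.0445,9.02,2.64017779,C_15_H_10_O_6_,Apigenin,,98.9,,inconsistent
275.1039,6.15,1.30711949,,,,,,na
279.2311,13.76,1.75842018,C_14_H_30_N_6_O,,,99.6,,inconsistent
281.2468,13.99,3.41644995,C_18_H_36_O_3_,,,77.7,,inconsistent
282.2510,13.99,3.53055616,,,,,,na
283.2614,14.36,2.88130084,C_14_H_32_N_6_,,,90.9,,consistent
285.0386,8.36,9.07714971,C_15_H_10_O_6_,Luteolin,Flavone,95.9,PM000420,inconsistent
286.0441,8.50,1.61411498,,,,,,na
287.2212,10.64,5.0420702,C_16_H_32_O_4_,,,90.6,,inconsistent
293.2108,12.78,4.11240994,,,,,,na
294.2158,12.84,1.05069407,C_18_H_34_O_3_,,,,,inconsistent
295.2255,12.81,2.38947953,C_16_H_12_O_6_,,,,,inconsistent
297.2417,13.64,1.15555122,,18-Hydroxyoleate,Lipid,97,literature,na
299.0558,9.11,1.06125804,C_16_H_30_O_5_,Chrysoeriol,Flavone,92.1,BS003342,inconsistent
299.1136,4.50,2.42334052,C_5_H_10_N_10_O_6_,,,,,inconsistent
301.2009,10.45,2.5807432,C_18_H_30_O_4_,,,92.3,,inconsistent
305.0701,5.34,1.59445723,C_18_H_34_O_5_,,,94.3,,inconsistent
309.2069,12.08,1.20749047,,13(S)-Hydroperoxylinolenic acid,Lipid derivative,91.9,EQ331602,na
311.2220,12.14,1.00496969,C_14_H_20_O_8_,,,90.2,,inconsistent
313.2372,12.31,2.63234722,C_18_H_36_O_4_,,,,,inconsistent
315.1086,3.82,1.87543365,C_12_H_31_N_9_O,Cornoside,Monoterpenoid,82.2,literature,inconsistent
315.2516,12.68,5.75432159,C_18_H_32_O_5_,"(9R,10S)-Dihydroxystearate",Lipid,83.8,,inconsistent
316.2560,12.68,1.87253721,C_18_H_34_O_6_,,,99.6,,inconsistent
327.2165,9.86,1.8513419,C_18_H_34_O_5_,,,74.5,,inconsistent
327.2170,10.58,1.27970038,C_18_H_34_O_5_,,,89.4,,inconsistent
329.2309,9.90,8.7666785,C_18_H_36_O_5_,,,84.9,,inconsistent
329.2312,10.46,15.8827924,C_18_H_36_O_5_,,,85,,inconsistent
331.2397,10.58,3.15270061,C_20_H_18_O_5_,,,73.7,,inconsistent
331.2471,10.32,4.29045396,C_15_H_24_N_10_,"9,10,18-Trihydroxyoctadecanoic acid",Lipid,82.9,CB000003,inconsistent
337.1071,7.59,1.13852175,C_14_H_20_O_7_,,,98.7,,inconsistent
343.2103,9.76,5.61777449,C_18_H_34_O_6_,,,90.1,,inconsistent
345.1194,4.45,1.59752959,C_21_H_38_O_5_,Salidroside,Phenol,93.2,literature,inconsistent
345.2267,10.14,2.43118178,C_14_H_30_O_4_S,,,94.7,,inconsistent
351.2535,13.80,1.65705829,,,,90.7,,na
353.1979,14.39,1.32301547,C_29_H_14_N_2_,,,90.1,,inconsistent
353.2683,14.03,3.8098374,C_24_H_40_O_4_,,,,,inconsistent
389.1082,5.26,2.22477443,C_30_H_16_N_2_,,,98.7,,inconsistent
391.2846,13.98,1.54222771,C_30_H_16_N_2_,,,99.9,,inconsistent
403.1231,5.43,11.927081,C_10_H_24_N_6_O_9_S,,,97.7,,inconsistent
403.1241,6.21,1.51585553,C_27_H_19_NO_3_,,,93,,inconsistent
403.1248,4.90,1.70275032,C_22_H_22_N_2_O_6_,,,91.9,,inconsistent
404.1284,5.46,2.71837775,C_26_H_42_O_4_,,,83.2,,inconsistent
409.1404,9.40,1.02744581,C_25_H_36_O_6_,,,94.9,,inconsistent
417.2995,14.02,2.96165422,C_25_H_36_O_7_,,,86,,inconsistent
431.2417,12.15,4.06742772,C_30_H_48_O_3_,,,98.4,,inconsistent
447.2371,12.05,1.69705193,,,,79.9,,na
455.3500,13.59,7.58565491,C_30_H_48_O_4_,,,89.5,,inconsistent
465.3191,13.91,2.81214421,C_21_H_46_N_8_O_4_,,,,,inconsistent
471.3445,13.17,7.15603201,C_30_H_46_O_5_,,,88.3,,inconsistent
473.3526,13.15,1.17624378,C_26_H_44_N_6_O_3_,,,91.2,,inconsistent
485.3251,12.40,1.38424034,C_22_H_24_N_10_O_6_,,,94.9,,inconsistent
487.3408,12.62,1.05541295,C_26_H_28_N_4_O_8_,,,89.4,,inconsistent
523.1812,7.95,2.2817832,C_22_H_24_N_10_O_7_,,,92.5,,inconsistent
523.1823,6.69,1.98662549,C_31_H_28_N_4_S_3_,,,94.9,,inconsistent
539.1758,7.35,4.19041331,C_30_H_62_N_6_O_4_,,,93.2,,inconsistent
551.1401,7.20,1.30540864,C_27_H_30_N_4_O_9_,,,89.5,,inconsistent
551.4651,14.77,1.80521386,C_27_H_34_N_4_O_9_,,,94.5,,inconsistent
553.1923,8.17,1.01121826,C_27_H_26_N_4_O_10_,,,80.5,,inconsistent
557.2215,9.09,1.91276674,C_34_H_64_O_6_,,,92.1,,inconsistent
565.1570,7.80,1.48905009,C_37_H_72_S_2_,,,95.5,,inconsistent
567.4602,14.38,1.17748434,C_32_H_46_N_4_O_2_S_2_,,,91.2,,inconsistent
579.4967,15.89,1.53743162,C_36_H_65_O_6_,,,94,,inconsistent
581.2984,15.37,1.15630577,C_38_H_46_O_4_S,,,94.9,,inconsistent
593.4753,14.42,2.86762481,C_30_H_42_N_6_O_7_,,,87.7,,inconsistent
597.3028,14.89,1.26409343,C_26_H_28_N_10_O_9_,,,91.7,,inconsistent
597.3045,15.81,2.16408575,C_27_H_50_N_8_O_9_,,,90.4,,inconsistent
623.1956,6.31,6.10963709,C_36_H_38_N_4_O_8_S,,,93.1,,inconsistent
629.3615,3.80,1.63848932,C_36_H_38_N_4_O_8_S,,,87.2,,inconsistent
685.2318,6.70,11.0557952,C_37_H_34_N_8_O_4_S,,,94.3,,consistent
685.2332,8.13,4.26228369,C_36_H_38_N_4_O_8_S,,,94.8,,consistent
685.2340,7.49,2.87707627,C_34_H_44_N_2_O_9_S_2_,,,94.4,,inconsistent
685.2350,8.85,2.42497379,C_29_H_46_N_6_O_6_S_4_,,,95.6,,inconsistent
687.2405,6.71,2.44188861,C_37_H_40_N_4_O_9_S,,,94.7,,inconsistent
701.2282,6.27,3.26078709,C_39_H_48_O_10_S_3_,,,95.7,,inconsistent
715.2448,6.86,2.14610112,C_33_H_42_N_9_O_7_S_3_,,,95.2,,inconsistent
771.2324,7.56,6.88415023,C_39_H_44_N_4_O_7_S_3_,,,91.3,,inconsistent
772.2375,7.58,3.06952732,C_40_H_46_N_4_O_7_S_3_,,,90.7,,inconsistent
775.2283,7.13,5.04216623,C_32_H_42_N_10_O_10_S_2_,,,97.6,,inconsistent
789.2423,6.92,5.89403491,C_38_H_74_N_8_O_10_S,,,94.3,,inconsistent
789.2428,7.76,6.82049513,C_43_H_80_N_8_S_4_,,,94.8,,inconsistent
833.5162,13.97,1.10683778,C_6_H_5_O_2_,,,99,,inconsistent
835.5312,13.98,2.88542004,C_7_H_8_O_2_,,,96,,inconsistent
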