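printed_mz,printed_rt,vip,formula,analyte,compound_class,finder_score,reference,consistency
149.0088,0.99,1.908055,C_4_H_6_O_6_,Tartaric acid,Organic acids,92.8,KO001902,consistent
195.0504,0.98,4.165611,C_6_H_12_O_7_,Gluconic acid,Organic acids,88.6,KO000864,consistent
247.0249,5.13,1.542148,C_13_H_12_OS_2_,,,87.9,,consistent
255.2311,13.96,1.687796,C_16_H_32_O_2_,,,65.6,,inconsistent
265.1460,13.51,1.05701,C_12_H_26_O_4_S,,,79.3,,inconsistent
265.1475,14.05,1.072462,,,,88.4,,na
279.2309,13.79,6.86827,,,,92.5,,na
281.2465,14.03,7.233686,,,,91.4,,na
282.2507,14.01,2.547436,,,,89.4,,na
283.2635,14.34,1.250575,,,,78.5,,na
289.0702,5.24,12.24895,,,,82.6,,na
289.0705,4.50,14.487,C_15_H_14_O_6_,Catechin,Flavonoid,97.8,BS003014,consistent
291.0146,5.12,3.056952,C_13_H_8_O_8_,Brevifolincarboxylic acid,Polyphenol,92.5,literature,consistent
293.1240,5.22,1.667305,C_12_H_22_O_8_,,,89.9,,consistent
293.1791,15.70,1.215117,,,,,,na
295.2263,13.06,5.327168,,,,88.2,,na
297.2422,13.05,2.411256,C_18_H_34_O_3_,,,91.4,,consistent
300.9982,6.84,8.084582,,Ellagic acid,Polyphenol,92.2,NGA02837,na
301.0345,8.09,1.688408,C_15_H_10_O_7_,Quercetin,Flavonoid,93.5,PR100233,consistent
309.1727,14.34,1.722773,,,,,,na
311.2221,11.84,1.983825,,,,,,na
313.2368,12.20,8.325131,C_18_H_36_O_5_,Phloionolic acid,Triterpenoid,88.4,,inconsistent
314.2411,12.21,1.989586,C_12_H_29_N_9_O,,,,,consistent
315.0875,7.06,1.83894,C_17_H_16_O_6_,Persicogenin,Flavonoid,95.6,literature,consistent
315.2528,12.65,1.635675,,,,,,na
329.2327,10.38,1.132457,,,,,,na
341.1077,0.98,4.904493,,,,,,na
341.1086,1.80,1.266851,C_13_H_26_O_6_S_2_,,,82.2,,consistent
366.1190,5.82,1.098081,C_17_H_21_NO_8_,,,78.4,,consistent
380.9556,6.29,1.721243,C_15_H_10_O_6_S_3_,,,73.5,,consistent
387.1144,0.96,1.194701,,,,,,na
409.2340,14.65,1.206799,C_21_H_34_N_2_O_6_,,,78.8,,consistent
433.0408,6.51,2.234584,C_20_H_10_N_4_O_8_,,,75.5,,consistent
433.2336,14.26,2.630344,,,,,,na
439.0650,6.75,4.659214,C_22_H_16_O_10_,,,89.2,,consistent
439.0656,7.42,5.428307,C_22_H_16_O_10_,Amurensisin,Flavonoid,82.3,literature,consistent
439.0841,0.99,1.663483,C_15_H_16_N_6_O_10_,,,78.5,,consistent
440.0712,7.56,1.214139,C_16_H_11_N_9_O_7_,,,77.9,,consistent
441.0808,5.73,8.944765,C_22_H_18_O_8_,Epicatechin gallate,Flavonoid,81.3,BS003900,inconsistent
442.0865,5.87,2.155587,C_16_H_12_N_9_O_7_,,,82.2,,inconsistent
453.0676,4.78,1.773836,C_20_H_14_N_4_O_9_,,,83.4,,consistent
455.3510,13.60,2.632012,C_30_H_48_O_3_,Oleanolic acid,Triterpenoid acid,91.2,TY000153,consistent
461.2655,15.86,2.204115,C_25_H_38_N_2_O_6_,,,78.4,,consistent
463.0515,5.80,1.35816,C_21_H_12_N_4_O_9_,,,90.4,,consistent
476.2760,13.28,1.116856,C_25_H_39_N_3_O_6_,,,95.6,,consistent
477.0664,6.62,1.626783,C_21_H_18_O_13_,Quercetin 3-*O*-glucuronide (Miquelianin),Flavonoid glycoside,97.7,PR100978,consistent
479.0829,6.15,1.042092,C_21_H_20_O_13_,Myricetin-3-*O*-glucoside,Flavonoid glycoside,92.2,literature,consistent
571.2874,15.62,2.853407,C_40_H_36_N_4_,,,83.5,,consistent
577.1328,4.71,5.115305,C_27_H_17_N_10_O_6_,,,87.4,,inconsistent
577.1332,4.14,5.979778,C_27_H_18_N_10_O_6_,,,86.5,,consistent
577.1347,5.87,1.222666,C_23_H_26_N_6_O_10_S,,,88.2,,consistent
578.1376,4.74,1.749601,C_24_H_21_N_9_O_9_,,,92.1,,consistent
578.1378,4.11,2.151917,C_24_H_21_N_9_O_9_,,,86.4,,consistent
595.2864,14.96,2.240486,C_41_H_40_O_4_,,,98.1,,consistent
729.1441,4.95,2.275241,C_31_H_42_N_2_O_8_S_5_,,,84.2,,consistent
865.1964,4.97,1.576048,C_47_H_46_O_8_S_4_,,,83.4,,consistent
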