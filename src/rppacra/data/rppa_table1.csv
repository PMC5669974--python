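catalog_id,antibody,company,dilution,l_OS,s_OS,printed_ratio
9297,BAD (S155),Cell Signaling,1:100,0.00,15994.50,8.55
3073,c-Kit (Y703),Cell Signaling,1:50,9339.43,33189.87,3.55
4181,AMPKBbeta1 (S108),Cell Signaling,1:50,7072.72,20090.45,2.84
3391,cKit (Y719),Cell Signaling,1:100,13042.91,26635.48,2.04
4795,ErbB4/HER4 (111B2),Cell Signaling,1:50,18196.78,34200.64,1.88
9501,Caspase-9 cleaved (D330),Cell Signaling,1:50,16848.22,30031.45,1.78
9661,Caspase-3 cleaved (D175),Cell Signaling,1:50,8769.20,15599.59,1.78
3051,LKB1 (S428),Cell Signaling,1:100,22925.38,40538.19,1.77
44-792,EGFR (Y1148),Invitrogen,1:100,15214.44,25848.29,1.70
9121,MEK1/2 (S217/221),Cell Signaling,1:500,43914.49,67507.90,1.54
9295,BAD (S136),Cell Signaling,1:50,17890.05,24343.02,1.36
2101,Src family (Y416),Cell Signaling,1:200,31571.17,42192.58,1.34
9427,c-Raf (S338),Cell Signaling,1:200,28001.12,36680.49,1.31
44-1100,PRAS40 (T246),BioSource,1:1000,45706.67,59874.14,1.31
9455,4E-BP1 (T70),Cell Signaling,1:200,58104.61,70262.95,1.21
3024,IGF-1 Rec (Y1135/36)/Insulin Rec (Y1150/51),Cell Signaling,1:500,20702.29,23860.98,1.15
9181,Elk-1 (S383),Cell Signaling,1:100,20743.74,23388.52,1.13
2235,EGFR (Y992),Cell Signaling,1:50,38177.45,41772.79,1.09
9491,Caspase-7 cleaved (D198),Cell Signaling,1:50,32532.68,33860.36,1.04
34-8800,c-Kit (CD117),Zymed,1:500,31888.47,30333.25,0.95
2808,Survivin (71G4),Cell Signaling,1:100,21720.25,20373.70,0.94
07-018,p70S6 Kinase (T412),Upstate,1:500,12848.73,11684.29,0.91
3597,eIF2alpha (S51),Cell Signaling,1:500,4514.28,3873.83,0.86
2926,Cyclin D1 (G124-326),Cell Signaling,1:100,18958.36,15677.78,0.83
2386,IRS-1 (S612),Cell Signaling,1:200,25591.09,21036.21,0.82
2827,Bcl-2 (S70),Cell Signaling,1:50,38948.66,30638.11,0.79
9211,p38 MAP kinase (T180/Y182),Cell Signaling,1:100,35954.15,28001.12,0.78
44-794,EGFR (Y1173),Invitrogen,1:100,18901.57,14472.42,0.77
2632,Histone Deacetylase 3 (HDAC3),Cell Signaling,1:1000,8358.21,6173.37,0.74
9251,SAPK/JNK (T183/Y185),Cell Signaling,1:100,66171.19,47098.68,0.71
4431,a-Raf (S299),Cell Signaling,1:100,23623.56,16613.99,0.70
2971,mTOR (S2448),Cell Signaling,1:100,25336.48,17729.76,0.70
9331,GSK-3alpha/beta (S21/9),Cell Signaling,1:1000,56954.03,39735.50,0.70
3736,TNF-R1 (C25C1),Cell Signaling,1:50,9246.50,5302.85,0.57
9451,4E-BP1 (S65),Cell Signaling,1:50,27173.57,14559.52,0.54
9205,p70S6 Kinase (T389),Cell Signaling,1:100,42192.58,20952.22,0.50
4656,Cyclin A (BF683),Cell Signaling,1:50,33189.87,16171.41,0.49
9761,Caspase-6 cleaved (D162),Cell Signaling,1:50,23155.79,10938.02,0.47
2772,Bax,Cell Signaling,1:200,14016.64,6130.30,0.44
9134,Stat3 (S727),Cell Signaling,1:100,64215.49,25591.09,0.40
2232,EGFR,Cell Signaling,1:100,60475.90,23155.79,0.38
9101,ERK 1/2 (T202/Y204),Cell Signaling,1:1000,35242.23,13160.82,0.37
9208,p70S6 Kinase (S371),Cell Signaling,1:50,8324.85,2855.49,0.34
Sc-23950,Tubulin alpha acetylated (6-11B-1),SantaCruz,1:200,32208.97,9595.02,0.30
2696,b-Raf (S445),Cell Signaling,1:50,25336.48,6075.38,0.24
2772,Bak,Cell Signaling,1:200,4289.82,850.65,0.20
Sc-32793,NQO1,SantaCruz,1:200,12456.53,2109.06,0.17
610203,Cox-2,BD,1:200,41357.13,6136.44,0.15
SPA-894,Heme Oxygenase 1,Stressgen,1:500,45399.93,5084.75,0.11
3104,Smad2 (S245/250/255),Cell Signaling,1:100,33523.44,3203.50,0.10
2105,Src (Y527),Cell Signaling,1:200,36680.49,0.00,0.00
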