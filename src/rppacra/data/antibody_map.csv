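antibody,node,excluded
BAD (S155),BAD,false
c-Kit (Y703),cKIT,false
AMPKBbeta1 (S108),AMPK,false
cKit (Y719),cKIT,false
ErbB4/HER4 (111B2),ERBB4,false
Caspase-9 cleaved (D330),CASP,false
Caspase-3 cleaved (D175),CASP,false
LKB1 (S428),LKB1,false
EGFR (Y1148),EGFR,false
MEK1/2 (S217/221),MEK,false
BAD (S136),BAD,false
Src family (Y416),,true
c-Raf (S338),RAF,false
PRAS40 (T246),,true
4E-BP1 (T70),,true
IGF-1 Rec (Y1135/36)/Insulin Rec (Y1150/51),IGF1R,false
Elk-1 (S383),,true
EGFR (Y992),EGFR,false
Caspase-7 cleaved (D198),CASP,false
c-Kit (CD117),cKIT,true
Survivin (71G4),,true
p70S6 Kinase (T412),p70S6K,true
eIF2alpha (S51),,true
Cyclin D1 (G124-326),,true
IRS-1 (S612),,true
Bcl-2 (S70),,true
p38 MAP kinase (T180/Y182),,true
EGFR (Y1173),EGFR,false
Histone Deacetylase 3 (HDAC3),,true
SAPK/JNK (T183/Y185),,true
a-Raf (S299),RAF,false
mTOR (S2448),mTOR,false
GSK-3alpha/beta (S21/9),,true
TNF-R1 (C25C1),,true
4E-BP1 (S65),,true
p70S6 Kinase (T389),p70S6K,false
Cyclin A (BF683),,true
Caspase-6 cleaved (D162),CASP,true
Bax,,true
Stat3 (S727),,true
EGFR,EGFR,true
ERK 1/2 (T202/Y204),ERK,false
p70S6 Kinase (S371),p70S6K,false
Tubulin alpha acetylated (6-11B-1),,true
b-Raf (S445),RAF,false
Bak,,true
NQO1,,true
Cox-2,,true
Heme Oxygenase 1,,true
Smad2 (S245/250/255),,true
Src (Y527),,true
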