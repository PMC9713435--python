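group,relation,breed,hg,ht,ETSTY1,ETSTY2,ETSTY5,HSFY,RBMY,SRY,TSPY,UBA1Y,horse_id
1,grand_sire,Estonian Native,Non-Crown,DW4,5.3,6,3.7,0.94,2.6,1.77,15.8,3.5,BP387
1,sire,Estonian Native,Non-Crown,DW4,6.8,4.9,4,0.79,3,2,14.7,3.18,BP378
1,son,Estonian Native,Non-Crown,DW4,3.8,3.7,,,2.81,1.96,10.1,,BP364
2,grand_sire,Estonian Native,Crown,Ad,4,5.4,4.6,0.88,1.92,0.79,11.7,2.9,BP282
2,son,Estonian Native,Crown,Ad,5.6,4.5,4,0.99,2.85,1.55,12.9,3.07,BP388
3,sire,Estonian Native,Non-Crown,DW4,5,5,3.3,1.23,2.53,1.76,10.4,3.06,BP399
3,son,Estonian Native,Non-Crown,DW4,4.4,4.2,3.7,0.94,2.61,1.98,9.2,3.7,BP400
4,sire,Heck horse,Non-Crown,Pa,7.3,7.2,5.4,1.17,0.6,0.68,17.8,3.6,15758
4,son,Heck horse,Non-Crown,Pa,7.7,6.6,5.3,1.05,0.79,0.73,18.7,3.4,21150
5,cloned_brother,Arabian,,,4.37,4.62,4.73,1.07,1.74,0.99,11.9,3.11,H962
5,cloned_brother,Arabian,,,4.27,4.87,5.86,0.99,1.7,0.86,14.2,3.1,H963
6,scnt_donor,AQH,,,4.9,5.6,4.52,0.93,1.89,0.77,14.3,3.2,H396
6,cloned_brother,AQH,,,4.69,4.6,4.41,1.06,1.69,0.84,12.8,3.35,H391
6,cloned_brother,AQH,,,4.55,5.2,4.09,0.98,1.68,0.79,12,3.01,H392
6,cloned_brother,AQH,,,4.54,5.3,4.32,1.02,1.54,0.77,14.4,2.98,H393
6,cloned_brother,AQH,,,4.29,4.9,4.45,1.15,1.79,0.8,13.5,3.1,H394
6,cloned_brother,AQH,,,4.44,5.1,4.44,0.96,1.92,0.78,11.6,2.85,H395
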