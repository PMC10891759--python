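age_y,weight_kg,hematocrit,brain_rel,muscle_rel,adipose_rel
0.0,3.3,0.50,6.0,0.55,1.40
0.25,6.0,0.35,5.5,0.60,1.40
0.5,7.5,0.35,5.2,0.62,1.40
1.0,10.0,0.36,4.6,0.65,1.35
2.0,12.5,0.37,4.0,0.70,1.25
4.0,16.0,0.37,3.4,0.75,1.15
6.0,20.0,0.38,3.0,0.80,1.10
8.0,26.0,0.39,2.5,0.85,1.05
10.0,32.0,0.40,1.9,0.90,1.00
12.0,40.0,0.41,1.5,0.93,1.00
14.0,50.0,0.42,1.2,0.96,1.00
16.0,60.0,0.43,1.1,0.98,1.00
18.0,70.0,0.45,1.0,1.00,1.00
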