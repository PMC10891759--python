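organ,volume_L,flow_L_per_h,water,lipid,protein
lung,0.50,390.0,0.79,0.02,0.13
arterial_blood,1.70,0.0,0.80,0.006,0.16
venous_blood,3.90,0.0,0.80,0.006,0.16
brain,1.45,46.0,0.77,0.11,0.08
heart,0.33,15.0,0.73,0.03,0.17
muscle,29.00,65.0,0.76,0.03,0.19
adipose,18.00,19.0,0.18,0.79,0.02
skin,3.30,19.0,0.72,0.06,0.20
bone,10.50,19.0,0.45,0.07,0.20
kidney,0.31,74.0,0.78,0.05,0.15
liver,1.80,25.0,0.75,0.05,0.18
gut,1.65,43.0,0.75,0.06,0.16
spleen,0.15,8.0,0.78,0.03,0.17
pancreas,0.10,4.0,0.66,0.10,0.17
rest,3.00,53.0,0.70,0.10,0.18
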