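block,row,ref,route,dose_mg,per_kg,steady_state,n_obs,age_lo,age_hi,wt_lo,wt_hi,female_fraction,duration_h
iv_healthy,1,B36,iv_bolus,1,0,0,9,20,27,63.6,96.6,0.0,48
iv_healthy,2,B36,iv_bolus,2,0,0,9,20,27,63.6,96.6,0.0,48
iv_healthy,3,B36,iv_bolus,4,0,0,9,20,27,63.6,96.6,0.0,48
iv_healthy,4,B2,iv_bolus,2,0,0,4,43,54,76,111,0.0,48
oral_healthy,1,B2,oral,2,0,0,4,43,54,76,111,0.0,48
oral_healthy,2,B37,oral,60,0,0,7,24,42,42,70,0.571,48
oral_healthy,3,B37,oral,120,0,0,7,24,42,42,70,0.571,48
oral_healthy,4,B38,oral,80,0,0,8,21,24,73,84,0.0,48
oral_healthy,5,B38,oral,80,0,1,8,21,24,73,84,0.0,168
oral_healthy,6,B39,oral,30,0,0,11,21,29,47,98.6,0.0,48
oral_healthy,7,B40,oral,30,0,0,8,20,30,47.5,57.7,0.25,48
oral_healthy,8,B41,oral,30,0,0,12,20,63,48,98.9,0.5,48
oral_healthy,9,B42,oral,80,0,0,7,19,22,,,0.0,48
oral_healthy,10,B43,oral,80,0,0,8,18,23,51.8,74.9,0.5,48
oral_healthy,11,B44,oral,30,0,0,8,20,40,,,0.0,48
oral_healthy,12,B45,oral,30,0,0,13,21,63,51.3,88.5,0.538,48
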