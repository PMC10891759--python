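block,row,ref,dose_mg,per_kg,steady_state,cmax_pred,cmax_obs,ratio_cmax,auc_pred,auc_obs,ratio_auc,cl_pred,cl_obs,ratio_cl
iv_healthy,1,B36,1,0,0,52,44.6,1.16,78,82,0.95,10.5,10.6,0.99
iv_healthy,2,B36,2,0,0,104,81,1.28,157,172,0.91,19.3,20.4,0.94
iv_healthy,3,B36,4,0,0,209,165,1.26,314,306,1.02,46.2,44.4,1.04
iv_healthy,4,B2,2,0,0,86,71,1.19,128,179,0.71,13.5,14.1,0.96
oral_healthy,1,B2,2,0,0,4.7,4.4,1.07,71.9,68.6,1.04,40,56,0.71
oral_healthy,2,B37,60,0,0,112,105,1.06,973.5,972.7,1.00,2280,2820,0.80
oral_healthy,3,B37,120,0,0,138.4,143.3,0.96,1215,1992.5,0.60,7524,6240,1.20
oral_healthy,4,B38,80,0,0,125.2,115,1.08,1202.9,1011.3,1.18,3300,5360,0.61
oral_healthy,5,B38,80,0,1,125,151,0.82,1205,2224,0.54,1126,1440,0.78
oral_healthy,6,B39,30,0,0,125.7,117.8,1.05,1583,1830.7,0.79,1050,1020,1.02
oral_healthy,7,B40,30,0,0,53,51,1.03,722,716,1.00,1080,1140,0.94
oral_healthy,8,B41,30,0,0,52,64,0.81,802,838,0.95,930,960,0.96
oral_healthy,9,B42,80,0,0,108,80,1.35,1063,1071,0.99,3520,3840,0.91
oral_healthy,10,B43,80,0,0,125,117,1.07,1583,1813,0.87,3824,3040,1.25
oral_healthy,11,B44,30,0,0,64.4,63.2,1.01,830,840.4,0.98,960,990,0.96
oral_healthy,12,B45,30,0,0,55,52,1.05,759.7,765.5,0.99,1050,1020,1.02
iv_pediatric,1,B31,0.32,0,0,360,346,1.04,2255,2288,0.98,0.22,0.20,1.13
iv_pediatric,2,B31,0.33,0,0,191,1312,0.14,163,351,0.46,0.07,2.7,0.25
iv_pediatric,3,B31,1.475,0,0,198,99.5,1.98,244,337,0.72,57.5,47.2,1.21
oral_pediatric,1,B31,1.4,1,0,122,122.4,1.00,1281,1479.3,0.86,1.09,0.99,1.10
oral_pediatric,2,B31,1.4,1,0,1306,2148,0.60,140,275,0.51,1.82,3.40,0.53
oral_pediatric,3,B31,1.0,1,0,113,66.8,1.68,1013.6,799,1.26,0.66,0.87,0.75
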