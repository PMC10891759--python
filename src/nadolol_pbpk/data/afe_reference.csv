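group,parameter,afe
iv_healthy,cmax,0.87
iv_healthy,auc,0.56
iv_healthy,cl,0.98
oral_healthy,cmax,1.06
oral_healthy,auc,0.99
oral_healthy,cl,0.76
iv_pediatric,cmax,1.10
iv_pediatric,auc,0.98
iv_pediatric,cl,0.85
oral_pediatric,cmax,1.03
oral_pediatric,auc,0.76
oral_pediatric,cl,0.86
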