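medium,pH,solubility_ug_ml,sd_ug_ml,n
BR buffer pH 1.92,1.92,70.8,3.0,3
BR buffer pH 3.96,3.96,124,13,3
BR buffer pH 5.95,5.95,1910,70,3
BR buffer pH 7.17,7.17,32033,4135,3
BR buffer pH 8.02,8.02,300000,6500,3
1M NaOH,14,734000,30500,3
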