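formulation,cmax_individual_ug_ml,ratio_individual,tmax_individual_min,cmax_mean_ug_ml,ratio_mean
IBU,37.70,,82.1,28.25,
IBU-Na,47.00,1.25,35.2,44.00,1.56
IBU-Lys,49.90,1.32,35.1,42.75,1.51
IBU-lq,46.80,1.24,40.0,39.00,1.38
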