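formulation,B,MDT_min
IBU,1.759,71.55
IBU-Na,1.786,48.23
IBU-Lys,2.087,44.55
IBU-lq,2.274,52.18
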