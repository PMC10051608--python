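medium,pH,solubility_ug_ml,sd_ug_ml,n
FaSSGF blank,1.6,56.3,0.6,3
FaSSGF,1.6,56.0,0.5,3
FeSSGF-acetate,4.5,194,2,3
FeSSIF blank,5.0,416,12,3
FeSSIF,5.0,2103,56,3
FaSSIF blank,6.5,2513,15,3
FaSSIF,6.5,3160,31,3
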