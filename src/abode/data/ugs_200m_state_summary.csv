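state,wells,wells_with_rhu,pct_with_rhu_printed,uncapped_rhus,par_ppa,par_abode_capped,par_abode_uncapped,wilcoxon_z
CA,346,41,12,400,1216,895,939,3.11
MI,2394,668,28,2027,4740,4283,5158,6.64
NY,972,362,38,996,2495,2393,2691,3.81
OH,3318,1680,51,12014,27593,29184,31273,1.11
PA,1332,577,43,3709,4996,7421,9336,-5.99
WV,1472,488,33,1791,2012,3093,3853,0.79
TOTAL_PRINTED,9834,3816,41,20937,43052,48126,53250,12.5
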