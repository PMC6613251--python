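state,setback_ft,facilities_with_conflict,wells_with_conflict,rhus_in_setback,par_ppa,par_abode
MI,300,16,153,344,1277,532
NY,100,5,10,10,64,27
OH,100,9,65,83,724,401
PA,200,25,124,296,550,792
WV,200,14,92,172,246,419
TOTAL_PRINTED,,69,444,905,2861,2171
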