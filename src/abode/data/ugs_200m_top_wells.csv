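rank,storage_field,state,rhus,par_abode_capped,par_ppa,ppa_rank
1,Playa Del Rey,CA,150,341,375,1
2,Zane Storage,OH,142,318,259,83
3,Playa Del Rey,CA,107,283,234,64
4,Medina,OH,88,257,87,109
5,Oakford,PA,146,255,127,43
6,Murrysville,PA,98,244,201,10
7,Stark-Summit,OH,95,236,176,16
8,Stark-Summit,OH,81,222,66,155
9,Stark-Summit,OH,95,221,162,20
10,Stark-Summit,OH,77,221,203,9
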