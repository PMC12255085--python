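run_order,block,pH,salinity_ppt,cs_efficiency_pct,cs_time_h,mc_efficiency_pct,mc_time_h
1,1,10,5,92.35,24.92,81.86,42.92
2,1,4,5,96.14,19.5,88.7,35.42
3,1,4,35,93.38,25.08,82.88,39.25
4,1,7,20,75.46,42.75,62.38,68.83
5,1,7,20,75.42,42.75,62.68,68.83
6,1,10,35,90.57,28.42,75.3,47.83
7,1,7,20,75.43,42.67,62.6,68.75
8,2,7,20,75.42,42.75,62.67,68.75
9,2,7,12.5,74.75,44.75,63.16,69.33
10,2,7,20,75.51,42.83,62.39,68.92
11,2,5.5,20,82.42,33.5,72.01,55.5
12,2,7,27.5,75.3,44.17,59.92,70.25
13,2,7,20,75.56,42.75,62.67,68.58
14,2,8.5,20,80.05,36.5,67.99,61.75
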