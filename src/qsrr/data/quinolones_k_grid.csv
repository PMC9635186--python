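# Published reversed-phase HPLC retention factors (k) of 11 quinolones at five
# mobile-phase pH values; dead time t0 = 2.9 min. Transcribed from the source
# study's retention-factor table.
compound,ph2.2,ph3.5,ph5.2,ph6.5,ph8.2
Gatifloxacin,1.580,1.603,1.576,1.566,1.635
Lomefloxacin,1.405,1.560,1.501,0.920,1.035
Moxifloxacin,1.558,1.606,1.592,1.749,1.840
Nadifloxacin,2.121,2.148,2.114,2.036,1.685
Norfloxacin,1.191,1.162,1.192,1.158,0.384
Ofloxacin,1.032,1.176,1.559,1.836,1.885
Ciprofloxacin,1.142,1.363,1.294,1.153,0.646
Gemifloxacin,1.557,1.576,1.578,1.584,1.633
Enrofloxacin,1.622,1.567,1.591,2.468,1.973
Danofloxacin,1.370,1.551,1.572,1.822,1.668
Sparfloxacin,1.560,1.576,1.567,2.486,1.987
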