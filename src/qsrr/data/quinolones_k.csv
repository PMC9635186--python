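# The 21 quinolone major-microspecies observations used for QSRR modeling
# (one compound@pH pair per selected major microspecies), with the train/test
# membership reconstructed from the published prediction table (membership is
# inferred: the source study lists it only via the starred test rows).
# Retention factors k are dimensionless; dead time t0 = 2.9 min.
compound,ph,k,split
Lomefloxacin,6.5,0.920,train
Ciprofloxacin,6.5,1.153,train
Norfloxacin,3.5,1.162,train
Ofloxacin,3.5,1.176,train
Ciprofloxacin,3.5,1.363,train
Lomefloxacin,3.5,1.560,train
Gatifloxacin,6.5,1.566,train
Gemifloxacin,3.5,1.576,train
Gemifloxacin,6.5,1.584,train
Gatifloxacin,3.5,1.603,train
Moxifloxacin,3.5,1.606,train
Danofloxacin,8.2,1.668,train
Nadifloxacin,8.2,1.685,train
Moxifloxacin,6.5,1.749,train
Enrofloxacin,8.2,1.973,train
Nadifloxacin,3.5,2.148,train
Norfloxacin,6.5,1.158,test
Danofloxacin,3.5,1.551,test
Sparfloxacin,3.5,1.576,test
Enrofloxacin,2.2,1.622,test
Ofloxacin,8.2,1.885,test
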