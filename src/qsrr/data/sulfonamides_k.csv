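# Published reversed-phase HPLC retention factors (k) of 13 sulfonamides at
# three acetonitrile percentages (50/45/30 %, v/v); dead time t0 = 2.0 min.
# Train/test membership reconstructed from the published prediction table.
compound,acn_percent,k,split
Sulfacetamide Na,50,0.154,train
Sulfacetamide Na,45,0.203,train
Sulfacetamide Na,30,0.393,train
Sulfaguanidine,50,0.170,train
Sulfaguanidine,45,0.188,train
Sulfaguanidine,30,0.256,train
Sulfadiazine,50,0.174,train
Sulfadiazine,45,0.228,train
Sulfadiazine,30,0.443,train
Sulfaclozine,50,0.549,train
Sulfaclozine,45,0.752,train
Sulfaclozine,30,2.196,train
Sulfadimethoxine,50,0.419,train
Sulfadimethoxine,45,0.567,train
Sulfadimethoxine,30,1.433,train
Sulfadimidine,50,0.311,train
Sulfadimidine,45,0.389,train
Sulfadimidine,30,0.730,train
Sulfadoxine,50,0.395,train
Sulfadoxine,45,0.524,train
Sulfadoxine,30,1.276,train
Sulfathiazole,50,0.166,train
Sulfathiazole,45,0.221,train
Sulfathiazole,30,0.426,train
Sulfachloropyrazine Na,50,0.546,train
Sulfachloropyrazine Na,45,0.754,train
Sulfachloropyrazine Na,30,2.177,train
Sulfanilamide,50,0.154,train
Sulfanilamide,45,0.194,train
Sulfanilamide,30,0.295,train
Sulfamethoxazole,50,0.421,test
Sulfamethoxazole,45,0.568,test
Sulfamethoxazole,30,1.548,test
Sulfapyridine,50,0.306,test
Sulfapyridine,45,0.359,test
Sulfapyridine,30,0.597,test
Sulfaquinoxaline,50,0.519,test
Sulfaquinoxaline,45,0.716,test
Sulfaquinoxaline,30,2.221,test
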