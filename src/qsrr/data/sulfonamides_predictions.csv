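# Experimental and predicted retention factors (k) of the sulfonamide FFA-SVR
# model: calibration predictions, leave-10%-out CV predictions and external
# test-set predictions (residual = predicted - experimental). Transcribed from
# the source study; the 15 duplicated training rows of the published table are
# stored once, and test residuals (not printed at source) are computed from
# the printed experimental/predicted pair.
compound,acn_percent,split,k_exp,k_pred_cal,resid_cal,k_pred_cv,resid_cv,k_pred_test,resid_test
Sulfacetamide Na,50,train,0.154,0.153,-0.001,0.151,-0.002,,
Sulfacetamide Na,45,train,0.203,0.194,-0.009,0.171,-0.032,,
Sulfacetamide Na,30,train,0.393,0.385,-0.008,0.336,-0.057,,
Sulfaguanidine,50,train,0.170,0.178,0.009,0.212,0.042,,
Sulfaguanidine,45,train,0.188,0.181,-0.006,0.182,-0.006,,
Sulfaguanidine,30,train,0.256,0.267,0.011,0.458,0.202,,
Sulfadiazine,50,train,0.174,0.185,0.011,0.193,0.019,,
Sulfadiazine,45,train,0.228,0.237,0.010,0.236,0.008,,
Sulfadiazine,30,train,0.443,0.454,0.011,0.520,0.078,,
Sulfaclozine,50,train,0.549,0.528,-0.021,0.460,-0.088,,
Sulfaclozine,45,train,0.752,0.701,-0.051,0.657,-0.095,,
Sulfaclozine,30,train,2.196,1.310,-0.886,1.082,-1.114,,
Sulfadimethoxine,50,train,0.419,0.429,0.010,0.427,0.008,,
Sulfadimethoxine,45,train,0.567,0.576,0.009,0.602,0.035,,
Sulfadimethoxine,30,train,1.433,1.278,-0.155,1.006,-0.427,,
Sulfadimidine,50,train,0.311,0.299,-0.012,0.289,-0.022,,
Sulfadimidine,45,train,0.389,0.378,-0.010,0.352,-0.037,,
Sulfadimidine,30,train,0.730,0.643,-0.087,0.555,-0.175,,
Sulfadoxine,50,train,0.395,0.405,0.010,0.419,0.024,,
Sulfadoxine,45,train,0.524,0.540,0.017,0.569,0.046,,
Sulfadoxine,30,train,1.276,1.211,-0.065,0.962,-0.314,,
Sulfathiazole,50,train,0.166,0.224,0.058,0.242,0.076,,
Sulfathiazole,45,train,0.221,0.285,0.064,0.289,0.068,,
Sulfathiazole,30,train,0.426,0.521,0.095,0.574,0.148,,
Sulfachloropyrazine Na,50,train,0.546,0.568,0.022,0.623,0.078,,
Sulfachloropyrazine Na,45,train,0.754,0.742,-0.012,0.698,-0.056,,
Sulfachloropyrazine Na,30,train,2.177,1.233,-0.944,0.937,-1.240,,
Sulfanilamide,50,train,0.154,0.165,0.011,0.231,0.078,,
Sulfanilamide,45,train,0.194,0.183,-0.010,0.167,-0.026,,
Sulfanilamide,30,train,0.295,0.307,0.012,0.409,0.114,,
Sulfamethoxazole,50,test,0.421,,,,,0.248,-0.173
Sulfamethoxazole,45,test,0.568,,,,,0.322,-0.246
Sulfamethoxazole,30,test,1.548,,,,,0.644,-0.904
Sulfapyridine,50,test,0.306,,,,,0.283,-0.023
Sulfapyridine,45,test,0.359,,,,,0.306,-0.053
Sulfapyridine,30,test,0.597,,,,,0.443,-0.154
Sulfaquinoxaline,50,test,0.519,,,,,0.530,0.011
Sulfaquinoxaline,45,test,0.716,,,,,0.719,0.003
Sulfaquinoxaline,30,test,2.221,,,,,1.279,-0.942
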