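# Experimental and predicted retention factors (k) of the quinolone FFA-SVR
# model: calibration (training-set) predictions, leave-one-out CV predictions
# and external test-set predictions with their residuals
# (residual = predicted - experimental), transcribed from the source study.
compound,ph,split,k_exp,k_pred_cal,resid_cal,k_pred_cv,resid_cv,k_pred_test,resid_test
Lomefloxacin,6.5,train,0.920,1.175,0.255,1.247,0.327,,
Ciprofloxacin,6.5,train,1.153,1.164,0.011,1.262,0.109,,
Norfloxacin,3.5,train,1.162,1.255,0.093,1.342,0.180,,
Ofloxacin,3.5,train,1.176,1.261,0.085,1.385,0.209,,
Ciprofloxacin,3.5,train,1.363,1.330,-0.033,1.293,-0.070,,
Lomefloxacin,3.5,train,1.560,1.550,-0.010,1.401,-0.159,,
Gatifloxacin,6.5,train,1.566,1.555,-0.011,1.493,-0.073,,
Gemifloxacin,3.5,train,1.576,1.586,0.010,1.593,0.017,,
Gemifloxacin,6.5,train,1.584,1.575,-0.009,1.558,-0.026,,
Gatifloxacin,3.5,train,1.603,1.613,0.010,1.621,0.018,,
Moxifloxacin,3.5,train,1.606,1.616,0.010,1.638,0.032,,
Danofloxacin,8.2,train,1.668,1.659,-0.009,1.662,-0.006,,
Nadifloxacin,8.2,train,1.685,1.694,0.009,1.763,0.078,,
Moxifloxacin,6.5,train,1.749,1.739,-0.010,1.700,-0.049,,
Enrofloxacin,8.2,train,1.973,1.819,-0.154,1.773,-0.200,,
Nadifloxacin,3.5,train,2.148,1.828,-0.320,1.769,-0.379,,
Norfloxacin,6.5,test,1.158,,,,,1.149,-0.009
Danofloxacin,3.5,test,1.551,,,,,1.433,-0.118
Sparfloxacin,3.5,test,1.576,,,,,1.563,-0.013
Enrofloxacin,2.2,test,1.622,,,,,1.493,-0.129
Ofloxacin,8.2,test,1.885,,,,,1.603,-0.282
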