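name,nominal_water_content,manufacturer_swell_factor,manufacturer_n,lef_17h_mean,lef_17h_sd,lef_24h_mean,lef_24h_sd,ref_17h_mean,ref_17h_sd,ref_24h_mean,ref_24h_sd,n_17h_mean,n_17h_sd,n_24h_mean,n_24h_sd,lab_water_content_mean,lab_water_content_sd
C38,38,1.20,1.44,1.182,0.019,1.201,0.019,1.154,0.010,1.179,0.011,1.552,0.063,1.526,0.097,26.5,12.8
C55,55,1.35,1.41,1.206,0.067,1.218,0.070,1.180,0.067,1.209,0.080,1.461,0.043,1.418,0.427,33.1,15.6
C58,58,1.36,1.40,1.290,0.047,1.353,0.011,1.325,0.039,1.353,0.042,1.417,0.036,1.354,0.409,52.2,5.3
C67,67,1.47,1.39,1.428,0.027,1.452,0.017,1.337,0.052,1.389,0.055,1.399,0.028,1.388,0.439,60.7,2.4
C77,77,1.66,1.38,1.499,0.045,1.563,0.093,1.485,0.053,1.536,0.052,1.414,0.070,1.372,0.458,63.7,13.4
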