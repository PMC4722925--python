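cell_line,n_subfractions,dose_per_subfraction,total_dose,overall_time,experimental_mean,experimental_sd,theoretical_mean,theoretical_sd
F10B16,1,4,4,5,0.518,0.019,0.513,0.038
4T1,1,4,4,5,0.459,0.017,0.445,0.012
F10B16,2,2,4,15,0.535,0.027,0.534,0.036
4T1,2,2,4,15,0.506,0.018,0.505,0.048
F10B16,2,2,4,30,0.549,0.017,0.550,0.023
4T1,2,2,4,30,0.547,0.018,0.545,0.019
F10B16,2,2,4,60,0.570,0.016,0.569,0.029
4T1,2,2,4,60,0.588,0.017,0.587,0.042
F10B16,2,2,4,120,0.586,0.016,0.585,0.019
4T1,2,2,4,120,0.609,0.018,0.609,0.027
F10B16,2,2,4,180,0.590,0.018,0.590,0.054
4T1,2,2,4,180,0.612,0.019,0.612,0.038
F10B16,2,2,4,240,0.591,0.029,0.591,0.024
4T1,2,2,4,240,0.613,0.016,0.613,0.029
F10B16,4,1,4,30,0.546,0.026,0.542,0.038
4T1,4,1,4,30,0.546,0.017,0.529,0.035
F10B16,8,0.5,4,30,0.549,0.015,0.540,0.034
4T1,8,0.5,4,30,0.547,0.026,0.523,0.043
F10B16,4,1,4,60,0.570,0.017,0.567,0.047
4T1,4,1,4,60,0.585,0.017,0.595,0.047
F10B16,8,0.5,4,60,0.570,0.016,0.564,0.028
4T1,8,0.5,4,60,0.583,0.008,0.589,0.038
F10B16,4,1,4,240,0.598,0.018,0.622,0.024
4T1,4,1,4,240,0.653,0.027,0.706,0.038
F10B16,8,0.5,4,240,0.607,0.008,0.627,0.023
4T1,8,0.5,4,240,0.674,0.008,0.732,0.042
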