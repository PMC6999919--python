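quantity,unit,coefficient,coef_ci_lo,coef_ci_hi,exponent,exp_ci_lo,exp_ci_hi
forelimb_mass,kg,5.82e-2,4.61e-2,7.34e-2,1.00,0.93,1.08
forelimb_com_length,m,5.64e-2,4.98e-2,6.38e-2,0.36,0.32,0.40
forelimb_moi,kg m^2,2.52e-4,1.61e-4,3.95e-4,1.75,1.60,1.89
triceps_mass,kg,6.20e-3,5.54e-3,6.94e-3,1.11,1.07,1.15
triceps_length,m,1.87e-2,1.72e-2,2.04e-2,0.33,0.29,0.37
triceps_moment_arm,m,8.70e-3,8.13e-3,9.31e-3,0.41,0.38,0.44
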