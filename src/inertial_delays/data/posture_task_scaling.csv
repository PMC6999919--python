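quantity,unit,coefficient,coef_ci_lo,coef_ci_hi,exponent,exp_ci_lo,exp_ci_hi
forelimb_length,m,1.61e-1,1.42e-1,1.82e-1,0.38,0.34,0.42
hindlimb_length,m,1.63e-1,1.47e-1,1.80e-1,0.36,0.32,0.39
ankle_extensor_mass,kg,5.10e-3,4.40e-3,5.92e-3,0.97,0.92,1.02
ankle_extensor_length,m,1.06e-2,8.98e-3,1.25e-2,0.14,0.06,0.22
ankle_extensor_moment_arm,m,9.40e-3,8.79e-3,1.01e-2,0.38,0.35,0.41
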