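tissue,wavelength_nm,mu_s,mu_s_sd,mu_a,mu_a_sd,g,g_sd,mu_s_prime,mu_s_prime_sd,refractive_index,n_samples
cancer,457,267,19,6.3,3.1,0.82,0.02,46.2,2.0,1.33,3
cancer,890,195,26,6.6,1.5,0.86,0.02,29,3.3,1.33,3
normal,457,172,39,7.3,2.4,0.83,0.01,29.6,6.5,1.33,5
normal,890,161,43,5.6,1.2,0.94,0.01,10.3,3.8,1.33,5
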