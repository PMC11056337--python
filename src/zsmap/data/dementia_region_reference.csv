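region,group,n_subjects,z_unmasked,z_unmasked_sd,z_masked,z_masked_sd,rate_pct,rate_sd
superior_parietal,normal,15,1.12,0.30,0.97,0.26,12.6,9.3
angular,normal,15,1.12,0.34,0.93,0.32,17.4,14.8
supramarginal,normal,15,0.99,0.27,0.80,0.24,19.1,16.2
precuneus,normal,15,1.03,0.28,0.89,0.22,11.8,10.0
posterior_cingulate,normal,15,0.78,0.29,0.70,0.24,9.1,9.1
superior_parietal,mci,40,1.97,0.75,1.73,0.65,12.5,4.4
angular,mci,40,1.25,0.48,1.09,0.43,12.4,5.5
supramarginal,mci,40,1.13,0.38,1.02,0.35,10.0,7.0
precuneus,mci,40,1.76,0.58,1.55,0.49,11.5,4.3
posterior_cingulate,mci,40,1.68,0.70,1.60,0.69,5.9,7.2
superior_parietal,ad,16,1.73,0.47,1.48,0.43,14.6,7.8
angular,ad,16,1.98,0.74,1.80,0.76,10.3,5.5
supramarginal,ad,16,1.57,0.63,1.43,0.60,9.6,4.4
precuneus,ad,16,1.56,0.37,1.37,0.35,12.1,6.0
posterior_cingulate,ad,16,1.59,0.59,1.51,0.58,5.9,5.8
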