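quantity,pre_mean,pre_sd,post_mean,post_sd
pcai,1.00,0.1,1.02,0.07
pca_total,2.04,0.14,2.58,0.25
pca_total_over_pcai,,,2.53,0.28
ph,7.47,0.05,7.48,0.04
bicarbonate,26.4,4.9,27.6,5.5
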