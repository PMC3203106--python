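label_age,genotype,rudiment,brdu_t2h,brdu_t24h,ect_fraction_t2h,mr_fraction_t2h,v_t2h,v_t24h,printed_dv_exp,printed_dv_obs,printed_note
E11.5,wt,1,18340,103804,0.13,0.036,97777,220554,1.29,1.26,1
E11.5,wt,3,18659,87785,0.17,0.031,131174,201646,0.66,0.54,1
E11.5,wt,4,27841,199576,0.16,0.065,95857,191118,2.50,0.99,1
E11.5,mt,1,11775,73650,0.17,0.034,74470,148758,1.06,1.00,
E11.5,mt,2,3074,97784,0.24,0.052,14155,115751,6.58,7.18,
E12.5,wt,1,44606,74388,0.26,0.059,220554,336218,0.15,0.52,2
E12.5,wt,2,19050,47805,0.20,0.034,154765,320787,0.26,1.07,2
E12.5,wt,3,34501,71186,0.27,0.069,201646,345423,0.27,0.71,2
E12.5,wt,4,21156,68000,0.21,0.023,191118,401653,0.24,1.10,2
E12.5,wt,5,31123,62825,0.17,0.040,163703,265012,0.24,0.62,2
E12.5,mt,1,56019,99624,0.18,0.094,148758,274814,0.41,0.85,3
E12.5,mt,2,51318,71708,0.18,0.063,115751,147332,0.14,0.27,3
E12.5,mt,4,62714,85049,0.21,0.084,131015,192489,0.14,0.47,3
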