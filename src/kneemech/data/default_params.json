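{
 "bounds": {
  "fp_femur_dx": [
   -6.0,
   6.0
  ],
  "fp_femur_dy": [
   -6.0,
   6.0
  ],
  "fp_femur_dz": [
   -18.0,
   18.0
  ],
  "fp_tibia_dx": [
   -14.0,
   6.0
  ],
  "fp_tibia_dz": [
   -18.0,
   18.0
  ],
  "k_ACL_am": [
   100.0,
   30000.0
  ],
  "k_ACL_pl": [
   100.0,
   30000.0
  ],
  "k_LCL": [
   100.0,
   120000.0
  ],
  "k_MCL": [
   100.0,
   120000.0
  ],
  "k_PCL": [
   100.0,
   60000.0
  ],
  "k_ap_lateral": [
   0.05,
   300.0
  ],
  "k_ap_medial": [
   0.05,
   300.0
  ],
  "k_graft": [
   500.0,
   30000.0
  ],
  "k_post_lateral": [
   0.05,
   300.0
  ],
  "k_post_medial": [
   0.05,
   300.0
  ],
  "k_tors_0": [
   50.0,
   10000.0
  ],
  "k_tors_90": [
   50.0,
   10000.0
  ],
  "pretension_fix0": [
   0.0,
   160.0
  ],
  "pretension_fix30": [
   0.0,
   160.0
  ],
  "s_ACL_am": [
   0.8,
   1.2
  ],
  "s_ACL_pl": [
   0.8,
   1.2
  ],
  "s_LCL": [
   0.8,
   1.2
  ],
  "s_MCL": [
   0.8,
   1.2
  ],
  "s_PCL": [
   0.8,
   1.2
  ],
  "tau_tors": [
   3.0,
   200.0
  ]
 },
 "values": {
  "fp_femur_dx": 2.0729,
  "fp_femur_dy": 0.9812,
  "fp_femur_dz": -17.8878,
  "fp_tibia_dx": -6.5465,
  "fp_tibia_dz": -18.0,
  "k_ACL_am": 715.7872,
  "k_ACL_pl": 8178.227,
  "k_LCL": 119916.2771,
  "k_MCL": 119998.101,
  "k_PCL": 29998.3409,
  "k_ap_lateral": 22.5648,
  "k_ap_medial": 0.0629,
  "k_graft": 3678.2628,
  "k_post_lateral": 47.7104,
  "k_post_medial": 0.05,
  "k_tors_0": 3199.1505,
  "k_tors_90": 1466.4954,
  "pretension_fix0": 0.0001,
  "pretension_fix30": 0.4853,
  "s_ACL_am": 0.8,
  "s_ACL_pl": 1.1452,
  "s_LCL": 0.9514,
  "s_MCL": 0.9774,
  "s_PCL": 1.1291,
  "tau_tors": 11.3193
 }
}
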