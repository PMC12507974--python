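{
 "meta": {
  "n_reps": 150,
  "seed": 20260101,
  "n_samples": 18000,
  "trim_samples": 800,
  "dfa": "DFA-1, 20 log windows, 16..N/4"
 },
 "table": {
  "hurst": [
   0.1,
   0.15,
   0.2,
   0.25,
   0.3,
   0.35,
   0.4,
   0.45,
   0.5,
   0.55,
   0.6,
   0.65,
   0.7
  ],
  "alpha_rs": [
   1.0256949884256183,
   1.0951265969665835,
   1.155906060518549,
   1.2130700656033548,
   1.264723307414785,
   1.3264529200370092,
   1.3760821689016112,
   1.4262629162607274,
   1.4840032522917352,
   1.5379936541532175,
   1.595787222762299,
   1.6477309452282365,
   1.7012443120528915
  ],
  "alpha_rs_sd": [
   0.044594848355547216,
   0.040424383017233265,
   0.03571053168502611,
   0.0396356266900901,
   0.038596296972936414,
   0.03844646563849417,
   0.04056206483485419,
   0.040210998553243775,
   0.040802640168286275,
   0.044952845458522184,
   0.04533935818654364,
   0.052989880388692796,
   0.04838330556224557
  ],
  "unit_mean_rs": [
   3.0663645053349358,
   4.857806629013586,
   7.628709238417827,
   11.999032334477121,
   18.34997610930821,
   30.615468742862966,
   46.93078708150599,
   72.46407300282608,
   113.41209206734894,
   184.56301945278386,
   319.2504316702959,
   490.382877797881,
   723.5173515519484
  ],
  "unit_mean_rs_cv": [
   0.3267648201632397,
   0.2957344537301486,
   0.2963286273039849,
   0.3231421881884117,
   0.3377628531515146,
   0.33942685218165297,
   0.3852154638863106,
   0.3267313092043165,
   0.4211945838195983,
   0.39948797874272196,
   0.43990858948156225,
   0.4979699539624464,
   0.46143539276872975
  ]
 }
}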