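{
 "human": {
  "producer": "human",
  "p_surv": 0.42,
  "length_decay": 0.75,
  "p_syn": 0.3,
  "aoa_shift": 0.0,
  "length0": 140,
  "negation_rate_happy": 0.025,
  "negation_rate_sad": 0.05,
  "rating": {"beta0": 0.0, "beta1": 0.0, "gamma": 0.0, "sigma": 0.3, "tau": 1.0}
 },
 "llm": {
  "producer": "llm",
  "p_surv": 0.9,
  "length_decay": 0.95,
  "p_syn": 0.4,
  "aoa_shift": 1.5,
  "length0": 140,
  "negation_rate_happy": 0.008,
  "negation_rate_sad": 0.016,
  "rating": {"beta0": 0.0, "beta1": 0.0, "gamma": 0.0, "sigma": 0.3, "tau": 1.0}
 }
}
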