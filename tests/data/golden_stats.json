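{"rank_sum_exact":{"a":[0.86,0.91,0.78,0.88,0.83,0.95,0.81,0.9],"b":[0.36,0.41,0.29,0.33],"W":32,"p":0.00404040404040404},"rank_sum_asymptotic":{"a":[0.61,0.55,0.72,0.64,0.58,0.66,0.7,0.52,0.63,0.69,0.57,0.74],"b":[0.6,0.59,0.62,0.65,0.61,0.58,0.66,0.63,0.57,0.64,0.68,0.56],"W":84,"p":0.506165287947877},"chi_square":{"n_cooperate":114,"n_total":150,"statistic":40.56,"p":1.90670214565835e-10},"anova":{"groups":[[0.76,0.81,0.7,0.79,0.74,0.77,0.72,0.8],[0.1,0.12,0.08,0.11,0.09,0.13,0.1,0.07],[0.1,0.09,0.12,0.08,0.11,0.1,0.13,0.09],[0.04,0.03,0.05,0.02,0.06,0.04,0.03,0.05]],"F":1569.53393438517,"p":2.75015402593183e-31}}
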