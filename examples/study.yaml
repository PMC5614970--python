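# Reduced Monte Carlo study configuration.
# The full factorial design uses cn_list: [40, 100, 300],
# cs_list: [3, 30, 200], icc_list: [0.1, 0.3, 0.5, 0.7, 0.9] and
# replications: 1000; this desk-scale version runs in a few minutes.
cn_list: [40]
cs_list: [3, 30]
icc_list: [0.1, 0.3, 0.5]
replications: 50
seed: 314159
specs: [2MLR, 1MLR, 2MaxB, 2MaxW, 2Miss]
compute_indices: true
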