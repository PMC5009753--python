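variant: model0-plasmid
K_ii: 25.0
K_ir: 5.0
K_b1: 0.05
K_b2: 0.2291287847477921
K_b3: 0.05
K_b4: 0.15411035007422444
K_s1: 10.0
K_s2: 2.1
K_s3: 10.0
K_s4: 0.95
K_r1: 1.0
K_r2: 1.0
K_inh: 0.0005
kf_ii: 0.01
kf_ir: 0.01
kf_b1: 0.01
kf_b2: 0.01
kf_b3: 0.01
kf_b4: 0.01
kf_s1: 0.01856143491222374
kf_s2: 0.005
kf_s3: 0.11713185623238516
kf_s4: 0.005
kf_r1: 0.01
kf_r2: 0.01
kf_inh: 0.001
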