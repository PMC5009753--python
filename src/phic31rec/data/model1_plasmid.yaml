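variant: model1-plasmid
K_ii: 25.0
K_ir: 5.0
K_b1: 0.05
K_b2: 0.1
K_b3: 0.05
K_b4: 0.05
K_s1: 10.0
K_s2: 0.13795087521195426
K_s3: 10.0
K_s4: 0.04820953608520371
K_r1: 0.1386448484185206
K_r2: 0.09404504080057713
K_inh: 0.0005
K_mod: 20.913744302366364
K_modr: 22.056223223414506
kf_ii: 0.01
kf_ir: 0.01
kf_b1: 0.01
kf_b2: 0.01
kf_b3: 0.01
kf_b4: 0.01
kf_s1: 0.01856143491222374
kf_s2: 2.9414478044316927e-07
kf_s3: 0.11713185623238516
kf_s4: 2.0852690963026354e-06
kf_r1: 0.009710500484611929
kf_r2: 0.007699429772094394
kf_inh: 0.001
kf_mod: 0.011193260696577825
kf_modr: 0.014661013874549655
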