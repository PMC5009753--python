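variant: model1-linear
K_ii: 25.0
K_ir: 5.0
K_b1: 0.05
K_b2: 0.1
K_b3: 0.05
K_b4: 0.05
K_s1: 0.2
K_s2: 6.897543760597728
K_s3: 0.2
K_s4: 2.4104768042601887
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
kf_s1: 0.002
kf_s2: 2.9414478044316927e-07
kf_s3: 0.002
kf_s4: 2.0852690963026354e-06
kf_r1: 0.00020411125705924123
kf_r2: 0.00016183926790508152
kf_inh: 0.001
kf_mod: 0.011193260696577825
kf_modr: 0.014661013874549655
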