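# Group-typical VPP parameter means and SDs (natural scale).
# HC: healthy controls (n=39); MUD: methamphetamine use disorder (n=50);
# MUD_t_pre / MUD_t_post: the treated subgroup (n=24) before / after rTMS.
groups:
  HC:
    A: [0.04, 0.01]
    alpha: [0.95, 0.05]
    cons: [1.62, 0.10]
    lam: [0.26, 0.16]
    epP: [0.25, 1.18]
    epN: [-0.50, 1.23]
    K: [0.40, 0.17]
    w: [0.74, 0.03]
  MUD:
    A: [0.17, 0.07]
    alpha: [1.10, 0.07]
    cons: [1.01, 0.20]
    lam: [0.10, 0.18]
    epP: [0.86, 1.81]
    epN: [-0.21, 1.31]
    K: [0.36, 0.17]
    w: [0.64, 0.12]
  MUD_t_pre:
    A: [0.19, 0.08]
    alpha: [1.09, 0.09]
    cons: [1.01, 0.18]
    lam: [0.13, 0.25]
    epP: [0.62, 1.89]
    epN: [-0.28, 1.23]
    K: [0.34, 0.16]
    w: [0.65, 0.11]
  MUD_t_post:
    A: [0.05, 0.002]
    alpha: [0.71, 0.05]
    cons: [1.14, 0.09]
    lam: [0.51, 0.15]
    epP: [1.03, 0.76]
    epN: [0.21, 1.05]
    K: [0.47, 0.15]
    w: [0.54, 0.01]
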