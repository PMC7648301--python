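# Patient Activation Measure (PAM-13) four-level conversion cut-points
# (Insignia Health / Hibbard et al. published boundaries).
# Level 1: <= 47.0; level 2: 47.1-55.1; level 3: 55.2-67.0; level 4: >= 67.1
version: "pam/1.0"
level1_max: 47.0
level2_max: 55.1
level3_max: 67.0
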