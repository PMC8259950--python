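# Default affinity-model parameters (versioned with the package).
# S(window) = w0 + w_pwm * PWM + w_ta * mean(ta_richness)
#           + w_mg * mean(minor_groove_width) + w_melt * mean(melting)
# w0 absorbs non-specific TBP-DNA affinity; the negative w_mg rewards narrow
# (deformable) minor grooves and the positive w_melt rewards easy local
# melting, both features of TBP-bound TATA DNA. Weights were calibrated once
# on the synthetic promoter generator so that consensus-damaging core
# mutations are called as significant deficiency at alpha = 0.05.
version: 1
w0: 29.0
w_pwm: 1.0
w_ta: 0.2
w_mg: -0.1
w_melt: 0.1
L: 15
scan_both_strands: true
top_k_for_se: 10
alpha: 0.05
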