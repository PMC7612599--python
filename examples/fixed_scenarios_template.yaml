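# Template for the eight named fixed toxicity scenarios.
#
# The exact parameter vectors of these scenarios live in the study's
# supplementary material and are not bundled; fill in every `null` before
# use.  `load_fixed_scenarios` rejects files with placeholder entries, so
# this template cannot be consumed accidentally.
#
# Families: logistic5 (alpha01, alpha11, alpha02, alpha12, eta),
#           bailey    (alpha01, alpha11, beta1, beta2, beta3),
#           bliss7    (beta1..beta7).
reference_doses: {m_star: 60.0, b_star: 30.0}
scenarios:
  - name: Safe
    family: logistic5
    params: {alpha01: null, alpha11: null, alpha02: null, alpha12: null, eta: null}
  - name: Low Toxicity 1
    family: logistic5
    params: {alpha01: null, alpha11: null, alpha02: null, alpha12: null, eta: null}
  - name: Low Toxicity 2
    family: logistic5
    params: {alpha01: null, alpha11: null, alpha02: null, alpha12: null, eta: null}
  - name: Medium Toxicity 1
    family: logistic5
    params: {alpha01: null, alpha11: null, alpha02: null, alpha12: null, eta: null}
  - name: Medium Toxicity 2
    family: logistic5
    # the interaction of this scenario is nearly additive: eta must be 0.10
    params: {alpha01: null, alpha11: null, alpha02: null, alpha12: null, eta: 0.10}
  - name: High Toxicity 1
    family: logistic5
    params: {alpha01: null, alpha11: null, alpha02: null, alpha12: null, eta: null}
  - name: High Toxicity 2
    family: logistic5
    params: {alpha01: null, alpha11: null, alpha02: null, alpha12: null, eta: null}
  - name: Unsafe
    family: logistic5
    params: {alpha01: null, alpha11: null, alpha02: null, alpha12: null, eta: null}
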