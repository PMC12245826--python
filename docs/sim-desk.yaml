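# Example desk-profile study: Type I error and power for a 5-item test.
designs: [homogeneous]
J: [5]
delta_theta: [0.0, -0.5]
estimators:
  - wml
  - {method: eap, prior_mean: 0.0}
  - {method: eap, prior_mean: -0.5}
  - ctt
profile: desk
seed: 1
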