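# Reference fitted parameter set for the 5-s tone / 30-s flash
# peak-interval dataset. Tone-channel weights (W1-W6) were fitted to the
# averaged tone response, flash-channel weights (W7-W12) to the flash
# response with the tone channel frozen; the final integrator (W13, W14)
# is fixed throughout. Saliency constants apply on compound trials only.
W1: 0.2342
W2: -0.1774
W3: 57.3471
W4: 1.3228
W5: 9.7741
W6: 11.3814
W7: 0.00081236
W8: -0.000521
W9: 865.0088
W10: 1.1229
W11: 0.9659
W12: 1.6959
W13: 0.1
W14: 0.9
t_sat: 1.6
f_sat: 0.85
cutoff_a: -0.8632
cutoff_v: -0.2
epsilon: 0.01
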