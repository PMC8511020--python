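# Per-child WAZ effect sizes (σ-units) of nutrition interventions, with
# 95% confidence bounds, from the published meta-analytic literature on
# maternal and child undernutrition interventions (Bhutta and colleagues).
# These are external inputs to the intervention-equivalence calculation and
# can be edited; runs record which file was used.
interventions:
  - name: multiple_micronutrient_supplementation
    effect_size_sigma: 0.181
    ci_low: 0.126
    ci_high: 0.323
  - name: complementary_feeding
    effect_size_sigma: 0.337
    ci_low: 0.231
    ci_high: 0.735
  - name: nutrition_education
    effect_size_sigma: 0.337
    ci_low: 0.206
    ci_high: 0.933
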