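# Two milk-allowance plans for the same calf, starter and liquid diet.
# Ranges: initial_bw 20-60 kg; temperature -30 to 50 degC; weaning_age 10-120 d;
# horizon <= 100 d; up to 4 scenarios per comparison.
scenarios:
  - label: conventional-6L
    initial_bw: 40.0
    temperature: 20.0
    horizon: 80
    liquid:
      kind: whole_milk
      dm_fraction: 0.125
      me_density: 4.6
      cost_per_litre: 0.45
    starter:
      dm_fraction: 0.90
      cp_fraction: 0.22
      ndf_fraction: 0.15
      fat_fraction: 0.04
      ash_fraction: 0.07
      form: texturized
      cost_per_kg: 0.50
    plan:
      weaning_age: 56
      first_starter_offer_day: 3
      allowance_by_day:
        - [1, 6.0]
        - [43, 3.0]
  - label: accelerated-9L
    initial_bw: 40.0
    temperature: 20.0
    horizon: 80
    liquid:
      kind: whole_milk
      dm_fraction: 0.125
      me_density: 4.6
      cost_per_litre: 0.45
    starter:
      dm_fraction: 0.90
      cp_fraction: 0.22
      ndf_fraction: 0.15
      fat_fraction: 0.04
      ash_fraction: 0.07
      form: texturized
      cost_per_kg: 0.50
    plan:
      weaning_age: 56
      first_starter_offer_day: 3
      allowance_by_day:
        - [1, 9.0]
        - [43, 4.5]
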