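# UK front-of-pack (FOP) traffic-light banding criteria for FOOD, per 100 g.
# green: value <= green_max; amber: green_max < value <= amber_max; red: value > amber_max.
# portion_red: per-portion red override (grams per portion), applied only when the
# portion weighs more than 100 g.
schema: uk-fop-food
portion_override_threshold_g: 100.0
nutrients:
  fat:
    green_max: 3.0
    amber_max: 17.5
    portion_red: 21.0
  saturates:
    green_max: 1.5
    amber_max: 5.0
    portion_red: 6.0
  sugars:
    green_max: 5.0
    amber_max: 22.5
    portion_red: 27.0
  salt:
    green_max: 0.3
    amber_max: 1.5
    portion_red: 1.8
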