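# Four simulated communities spanning a wealth-to-environmental-justice
# gradient, exposed to lead via soil/dust ingestion.  C is the soil lead
# concentration (mg/kg), IR the soil ingestion rate (mg/day), EF the
# exposure factor, BW the average body weight (kg).
#
# Body weights and intake rates are derived from the wealthiest
# community's baseline (80 kg, 50 mg/day) by the multiplicative
# adjustments recorded next to each stored value; the loader checks the
# stored values against base * adjustment to guard against fixture drift.
#
# unit_conversion is the multiplier applied to the C * IR product before
# dividing by body weight.  1.0e-3 is the convention under which this
# fixture's reference ADD magnitudes (3.91e-4 ... 5.06 mg/kg-day) arise;
# the physically standard mg-soil-to-kg conversion would be 1.0e-6 and
# would scale every dose down by a factor of 1000.
unit_conversion: 1.0e-3
base:
  body_weight: 80.0
  intake_rate: 50.0
scenarios:
  - name: wealthiest_community
    concentration: 5.0
    intake_rate: 50.0
    exposed_hours_per_day: 3.0   # EF = 3/24 = 0.125 (tables often print 0.13)
    body_weight: 80.0
    adjustments: {body_weight: 1.00, intake_rate: 1.0}
    tags: [above-poverty, grocery-access, far-from-contamination]
  - name: middle_community_1
    concentration: 50.0
    intake_rate: 60.0
    exposure_factor: 0.25
    body_weight: 82.4
    adjustments: {body_weight: 1.03, intake_rate: 1.2}
    tags: [intermediate-proximity]
  - name: middle_community_2
    concentration: 500.0
    intake_rate: 75.0
    exposure_factor: 0.5
    body_weight: 83.2
    adjustments: {body_weight: 1.04, intake_rate: 1.5}
    tags: [intermediate-proximity]
  - name: ej_community
    concentration: 5000.0
    intake_rate: 85.0
    exposure_factor: 1.0
    body_weight: 84.0
    adjustments: {body_weight: 1.05, intake_rate: 1.7}
    tags: [poverty, food-desert, proximity-to-NPL, mining-impacted]
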