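# Calibrated default scenario.
# Generator noise parameters are tuned (scripts/tune_presets.py) so the
# control cohort's mean 15-day window differential lands near 2.20 F and the
# injured cohort, with the injury sizes below, near 3.59 F.
generator:
  n_study: 5
  n_control: 26
  days: 135
  wear_minutes_per_day_mean: 600.0
  wear_minutes_per_day_sd: 60.0
  baseline_temp_mean: 85.0
  baseline_temp_sd: 1.5
  bilateral_noise_sd: 1.95
  patient_noise_cv: 0.6
  circadian_amplitude: 1.5
  drift_sd: 0.3
  ambient_temp: 72.0
  seed: 0

injuries:
  # joint destruction with diffuse warmth, short run of hotspots before diagnosis
  - injury_type: charcot
    foot: right
    locations: all
    onset_day: 94
    diagnosis_day: 100
    peak_offset: 8.25
    ramp_days: 2
  # traumatic blister of the right hallux
  - injury_type: blister
    foot: right
    locations: [hallux]
    onset_day: 90
    diagnosis_day: 100
    peak_offset: 9.0
    ramp_days: 5
  # persistent hotspots at all 6 locations
  - injury_type: osteomyelitis
    foot: right
    locations: all
    onset_day: 85
    diagnosis_day: 100
    peak_offset: 7.5
    ramp_days: 10
  # fifth metatarsal head ulcer
  - injury_type: ulcer
    foot: right
    locations: [mts5]
    onset_day: 88
    diagnosis_day: 100
    peak_offset: 10.5
    ramp_days: 7
  # deep vein thrombosis, differential across the entire right foot
  - injury_type: dvt
    foot: right
    locations: all
    onset_day: 95
    diagnosis_day: 100
    peak_offset: 6.75
    ramp_days: 3

alerts:
  threshold: 4.0
  escalation_days: 5
  min_minutes: 30

window_days: 15
minutes_budget: 900
eligibility_min_wear_days: 50
min_minutes_per_day: 30
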