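# Study compounds: nicardipine (NC) and its cyclodextrin complexes.
# Durations in minutes, concentrations in ng/mL. The `reported` block
# carries the published rounded peak values of the reference analysis;
# they are inputs to the fold calibration and the Tmax-scaled validation
# (the calibration chain is defined on rounded values).
compounds:
  - name: NC
    t_half_gi_min: 30.0        # 0.5 h in the GI tract
    t_half_plasma_min: 96.0    # 1.6 h elimination half-life
    dissolution_time_min: 180.0
    cmax_exp_ng_ml: 69.64
    cmax_exp_sd_ng_ml: 8.57
    tmax_exp_min: 60.0
    reported:
      cmax_pre: 0.58
      tmax_pre: 0.07
      cmax_refined: 0.59
      tmax_refined: 0.52
  - name: NC/HPbCD
    t_half_gi_min: 240.0       # 4 h
    t_half_plasma_min: 329.4   # 5.49 h
    dissolution_time_min: 15.0
    cmax_exp_ng_ml: 39.65
    cmax_exp_sd_ng_ml: 1.11
    tmax_exp_min: 180.0
    reported:
      cmax_pre: 0.43
      tmax_pre: 0.4
      cmax_refined: 0.43
      tmax_refined: 1.98
  - name: NC/TAbCD
    t_half_gi_min: 132.0       # 2.2 h
    t_half_plasma_min: 442.8   # 7.38 h
    dissolution_time_min: 480.0
    cmax_exp_ng_ml: 18.25
    cmax_exp_sd_ng_ml: 0.74
    tmax_exp_min: 240.0
    reported:
      cmax_pre: 0.18
      tmax_pre: 0.44
      cmax_refined: 0.18
      tmax_refined: 2.34

# Default periodic dose regimens (hours). The base dose is the
# precalculated hydrophilic-complex concentration; dissolution scalings
# 1/12 and 1/32 follow from the dissolution-time ratios vs 15 min.
regimens:
  NC:
    dose_amount_ug_ml: 0.49
    period_h: 6.0
    pulse_shape: rectangular
    pulse_width_h: 0.5
    dissolution_scale: 0.08333333333333333   # 1/12
  NC/HPbCD:
    dose_amount_ug_ml: 0.49
    period_h: 24.0
    pulse_shape: rectangular
    pulse_width_h: 0.5
    dissolution_scale: 1.0
  NC/TAbCD:
    dose_amount_ug_ml: 0.49
    period_h: 24.0
    pulse_shape: rectangular
    pulse_width_h: 0.5
    dissolution_scale: 0.03125               # 1/32
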