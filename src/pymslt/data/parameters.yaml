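# Probabilistic sensitivity analysis parameter catalogue.
# Each entry pins one uncertain model input: distribution family, central
# value, uncertainty (sd, sd_frac of the central value, or a 95% interval
# whose width/3.92 gives the sd), a tornado group, an optional correlation
# group (0.75 rank correlation within a group), and the model input it
# perturbs.  Entries under `expansions` are templated per disease.
parameters:
  - name: p_smartphone
    family: beta
    central: 0.7442
    ci95: [0.5749, 0.8819]
    group: smartphone_access
    correlation_group: intervention
    target: uptake.p_smartphone
  - name: p_exposed
    family: beta
    central: 0.7794
    ci95: [0.70, 0.89]
    group: campaign_exposure
    correlation_group: intervention
    target: uptake.p_exposed
  - name: p_download
    family: beta
    central: 0.1346
    ci95: [0.025, 0.25]
    group: app_downloaded
    correlation_group: intervention
    target: uptake.p_download
  - name: p_regular_use
    family: beta
    central: 0.26
    sd_frac: 0.2
    group: regular_use
    target: uptake.p_regular_use
  - name: effect_size_kg
    family: normal
    central: -0.43
    ci95: [-0.61, -0.25]
    truncate_max: 0.0
    group: effect_size
    target: effect.delta_kg
  - name: bmi_decay_rate
    family: lognormal
    central: 0.03
    sd_frac: 0.2
    group: bmi_decay
    target: decay.rate
  - name: intervention_cost
    family: gamma
    central: 2883000
    sd_frac: 0.2
    group: intervention_costs
    correlation_group: intervention
    target: cost.total
  - name: tmrel_fraction
    family: uniform
    low: 0.0
    high: 1.0
    group: tmrel
    target: risk.tmrel_fraction
  - name: lag_noncancer_upper
    family: normal
    central: 5.0
    sd_frac: 0.2
    group: time_lags
    target: lag.noncancer_upper
  - name: lag_cancer_lower
    family: normal
    central: 10.0
    sd_frac: 0.2
    group: time_lags
    target: lag.cancer_lower
  - name: lag_cancer_upper
    family: normal
    central: 30.0
    sd_frac: 0.2
    group: time_lags
    target: lag.cancer_upper
  - name: pyld_multiplier
    family: lognormal
    central: 1.0
    sd_frac: 0.1
    group: morbidity
    target: morbidity.pyld
  - name: dr_multiplier
    family: normal
    central: 1.0
    sd_frac: 0.1
    group: morbidity
    target: morbidity.dr
  - name: base_cost_multiplier
    family: gamma
    central: 1.0
    sd_frac: 0.1
    group: health_system_costs
    target: cost.base
  - name: disease_cost_multiplier
    family: gamma
    central: 1.0
    sd_frac: 0.1
    group: health_system_costs
    target: cost.disease
  - name: height_male_maori
    family: normal
    central: 1.0
    sd_frac: 0.04
    group: heights
    target: height.male.maori
  - name: height_male_non_maori
    family: normal
    central: 1.0
    sd_frac: 0.04
    group: heights
    target: height.male.non_maori
  - name: height_female_maori
    family: normal
    central: 1.0
    sd_frac: 0.04
    group: heights
    target: height.female.maori
  - name: height_female_non_maori
    family: normal
    central: 1.0
    sd_frac: 0.04
    group: heights
    target: height.female.non_maori
expansions:
  - kind: disease_rates        # log-normal multiplier, sd 5% of the rate
    family: lognormal
    central: 1.0
    sd_frac: 0.05
    group: disease_rates
  - kind: disease_trends       # absolute offset on the annual trend
    family: normal
    central: 0.0
    sd: 0.005
    diabetes_sd: 0.015
    group: trends
  - kind: relative_risks       # multiplier on the log relative risk
    family: lognormal
    central: 1.0
    sd_frac: 0.1
    group: relative_risks
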