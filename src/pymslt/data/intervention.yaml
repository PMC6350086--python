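# Central intervention parameters and uncertainty bounds for the
# smartphone weight-loss app promotion campaign (NZ$, 2011 prices).
uptake:
  p_smartphone: 0.7442        # proportion of adults with smartphone access
  p_smartphone_ci: [0.5749, 0.8819]
  p_exposed: 0.7794           # proportion reached by the mass-media campaign
  p_exposed_ci: [0.70, 0.89]
  p_download: 0.1346          # proportion downloading a weight-loss app
  p_download_ci: [0.025, 0.25]
  p_regular_use: 0.26         # proportion using the app 10+ times
  p_regular_use_sd_frac: 0.2
# rounded flow-diagram stages used in the published reach worked example
# (78% of the 60% with smartphones ~ 46.8% of adults)
rounded_cascade:
  p_smartphone: 0.60
  p_exposed: 0.78
effect:
  delta_kg: -0.43             # incremental weight loss among regular users
  ci_95: [-0.61, -0.25]
decay:
  rate_per_month: 0.03        # BMI units regained per month post intervention
  sd_frac: 0.2
costs:
  web_promotion: 72000
  mass_media: 2791000
  app_identification: 20000
  sd_frac: 0.2
  correlation_with_uptake: 0.75
ppp_nzd_per_usd: 1.486        # NZ$ per US$ (2011 purchasing power parity)
cost_effectiveness_threshold_nzd: 45000
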