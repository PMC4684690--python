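# Dementia in German males: rate constants of the simulation study.
# All-cause mortality of the non-demented: Gompertz hazard with a 1%
# per-year secular decline (beta_time = -ln 1.01); dementia incidence
# log-linear in age from age 50, stable in calendar time; relative
# mortality of the demented constant at 2.63.
time_origin: 1960
incidence:
  beta0: -12.8
  beta_age: 0.11
  beta_time: 0.0
  min_age: 50.0
mortality_healthy:
  beta0: -9.0
  beta_age: 0.085
  beta_time: -0.009950330853155723  # -ln(1.01)
  min_age: 0.0
relative_mortality:
  constant: 2.63
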