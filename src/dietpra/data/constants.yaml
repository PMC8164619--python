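# Reference doses and regulatory limits for dietary cadmium.
# All doses are per kg body weight; concentrations in mg/kg fresh weight.
rfd_efsa: 0.36            # ug/kg bw/day, EFSA tolerable daily dose (TWI / 7, displayed)
twi_efsa: 2.5             # ug/kg bw/week, EFSA tolerable weekly intake
ptwi_jecfa: 7.0           # ug/kg bw/week, JECFA provisional tolerable weekly intake
ptmi_jecfa: 25.0          # ug/kg bw/month, JECFA provisional tolerable monthly intake
rfd_epa_water: 0.0005     # mg/kg/day, US EPA RfD for Cd in drinking water
rfd_epa_food: 0.001       # mg/kg/day, US EPA RfD for Cd in food
ml_taiwan: 0.4            # mg/kg, Taiwanese / Codex maximum level for Cd in rice
ml_china: 0.2             # mg/kg, Chinese maximum level for Cd in rice
loq_as_printed: 0.2       # mg/kg, nominal ICP-MS limit of quantification (kept as metadata;
                          # inconsistent with the observed mean and detection rate, so not
                          # used as the default censoring point)
censor_threshold_default: 0.002   # mg/kg, working censoring threshold for synthetic surveys
detect_rate_overall: 0.89         # fraction of survey samples with quantifiable Cd
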