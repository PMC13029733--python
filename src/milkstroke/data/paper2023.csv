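# milkstroke parameter set: 2023 Japanese baseline
# fatality_28day_men: 0.149
# fatality_28day_women: 0.157
# recurrence_rate_men: 0.282
# recurrence_rate_women: 0.248
# rr_per_200g: 0.82
# rr_ci_lower: 0.75
# rr_ci_upper: 0.90
# reference_dose_g: 200.0
# horizon_cycles: 10
# cycle_length_years: 1.0
# target_intake_g_day: 180.0
# discount_rate: 0.02
# exchange_rate_jpy_per_usd: 156.65
sex,age_band,population,dairy_g_day,incidence,incidence_lo,incidence_hi,prevalence,prevalence_lo,prevalence_hi,stroke_mort,stroke_mort_lo,stroke_mort_hi,allcause_mort,allcause_mort_lo,allcause_mort_hi,inpatient_usd,outpatient_usd,drug_usd
men,30-39,6798000,83.5,42.4,30.2,59.1,426.2,379.8,479.0,4.1,4.0,4.4,63.4,63.0,63.8,38753773,5584819,8315682
men,40-49,8303000,74.5,144.8,114.5,180.0,1148.8,1015.5,1285.2,15.9,15.2,16.5,139.5,138.4,140.7,179301284,21568832,29075266
men,50-59,9194000,83.9,270.2,208.8,335.3,2860.1,2543.8,3171.6,36.7,35.3,38.1,378.1,374.8,381.6,399335567,55544773,65120487
men,60-69,7292000,105.7,398.9,306.9,517.4,5464.0,4894.2,6027.6,79.6,75.6,83.1,1001.9,993.7,1010.4,644610740,103186945,110814964
men,70-79,7438000,120.2,560.9,424.8,724.5,8441.3,7570.3,9391.0,226.8,210.5,237.8,2708.6,2688.5,2729.5,1282319379,219073369,170304477
women,30-39,6469000,91.4,26.8,19.0,38.3,443.3,396.6,492.4,1.8,1.7,1.9,36.5,36.1,36.8,22116756,4338202,8299326
women,40-49,8073000,95.0,71.8,55.1,91.6,846.4,761.8,934.7,6.9,6.6,7.2,83.9,83.1,84.7,100988631,13597236,20728388
women,50-59,9084000,101.0,127.5,100.1,160.8,1709.1,1531.9,1895.0,14.7,13.9,15.4,195.0,193.1,196.8,226854157,31534389,38844180
women,60-69,7546000,128.0,218.0,170.9,276.6,3136.9,2845.7,3417.1,28.1,25.1,30.1,424.7,421.1,428.2,357676506,57217788,66258666
women,70-79,8646000,136.7,348.1,270.4,442.4,5182.2,4701.0,5708.6,96.1,78.4,106.0,1187.4,1178.0,1196.6,962304709,152430800,121238509
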