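# Default contrasts for the discovery cohort design: 13 comparisons across
# the four groups, also stratifying asthma by allergic status.  Discovery
# calls use nominal p < 0.05 with sex as an additive covariate.
comparisons:
  - &disc
    name: mild_asthma_vs_control
    group_a: mild_asthma
    group_b: control
    covariates: [sex]
    significance: nominal_p
  - {<<: *disc, name: severe_asthma_vs_control, group_a: severe_asthma}
  - {<<: *disc, name: copd_vs_control, group_a: copd}
  - {<<: *disc, name: mild_vs_severe_asthma, group_a: mild_asthma, group_b: severe_asthma}
  - {<<: *disc, name: asthma_vs_control, group_a: [mild_asthma, severe_asthma]}
  - {<<: *disc, name: asthma_vs_copd, group_a: [mild_asthma, severe_asthma], group_b: copd}
  - {<<: *disc, name: severe_asthma_vs_copd, group_a: severe_asthma, group_b: copd}
  - {<<: *disc, name: mild_asthma_vs_copd, group_a: mild_asthma, group_b: copd}
  - {<<: *disc, name: allergic_vs_nonallergic_asthma,
     group_a: {group: [mild_asthma, severe_asthma], allergic: true},
     group_b: {group: [mild_asthma, severe_asthma], allergic: false}}
  - {<<: *disc, name: allergic_asthma_vs_control,
     group_a: {group: [mild_asthma, severe_asthma], allergic: true}}
  - {<<: *disc, name: nonallergic_asthma_vs_control,
     group_a: {group: [mild_asthma, severe_asthma], allergic: false}}
  - {<<: *disc, name: allergic_asthma_vs_copd,
     group_a: {group: [mild_asthma, severe_asthma], allergic: true}, group_b: copd}
  - {<<: *disc, name: allergic_vs_nonallergic_all,
     group_a: {allergic: true}, group_b: {allergic: false}}
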