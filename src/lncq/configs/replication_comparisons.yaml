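# Default contrasts for the replication cohort design.  BH-adjusted p < 0.05
# defines significance; group_a minus group_b is the reported log2FC and
# group_a is the positive class for biomarker evaluation.
comparisons:
  - name: rhinitis_vs_copd
    group_a: allergic_rhinitis
    group_b: copd
  - name: rhinitis_vs_adult_control
    group_a: allergic_rhinitis
    group_b: adult_control
  - name: rhinitis_vs_adult_asthma
    group_a: allergic_rhinitis
    group_b: adult_asthma
  - name: rhinitis_vs_nonallergic_asthma
    group_a: allergic_rhinitis
    group_b: {group: adult_asthma, allergic: false}
  - name: allergic_vs_nonallergic_asthma
    group_a: {group: adult_asthma, allergic: true}
    group_b: {group: adult_asthma, allergic: false}
  - name: rhinitis_vs_allergic_asthma
    group_a: allergic_rhinitis
    group_b: {group: adult_asthma, allergic: true}
  - name: adult_asthma_vs_copd
    group_a: adult_asthma
    group_b: copd
  - name: adult_asthma_vs_adult_control
    group_a: adult_asthma
    group_b: adult_control
  - name: childhood_vs_adult_control
    group_a: childhood_control
    group_b: adult_control
  - name: childhood_asthma_vs_childhood_control
    group_a: childhood_asthma
    group_b: childhood_control
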