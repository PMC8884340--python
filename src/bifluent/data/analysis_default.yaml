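# Default analysis plan: the full statistical battery over a scored cohort.
anovas:
  - name: fds_language_by_group
    dv: fds
    conditions: [NS-L1, NS-L2]
    within: condition
    between: group
  - name: semantic_cluster_size
    dv: mean_cluster_size
    mode: semantic
    conditions: [SS, NS-L1, NS-L2, FS]
  - name: semantic_switches
    dv: n_switches
    mode: semantic
    conditions: [SS, NS-L1, NS-L2, FS]
  - name: phonemic_cluster_size
    dv: mean_cluster_size
    mode: phonemic
    conditions: [LF-L1, LF-L2]
  - name: phonemic_switches
    dv: n_switches
    mode: phonemic
    conditions: [LF-L1, LF-L2]

contrast_families:
  - name: semantic_switches_conditions_bpwa
    dv: n_switches
    group: BPWA
    mode: semantic
    paired: true
    pairs: [[SS, NS-L1], [SS, NS-L2], [SS, FS], [NS-L1, NS-L2], [NS-L1, FS], [NS-L2, FS]]
  - name: semantic_switches_conditions_hb
    dv: n_switches
    group: HB
    mode: semantic
    paired: true
    pairs: [[SS, NS-L1], [SS, NS-L2], [SS, FS], [NS-L1, NS-L2], [NS-L1, FS], [NS-L2, FS]]
  - name: switches_group_per_condition
    dv: n_switches
    mode: semantic
    paired: false
    between: [BPWA, HB]
    conditions: [SS, NS-L1, NS-L2, FS]
  - name: correct_group_per_condition
    dv: mean_correct
    paired: false
    between: [BPWA, HB]
    conditions: [SS, NS-L1, NS-L2, FS, LF-L1, LF-L2]

pca:
  - name: bpwa_l1_luq
    group: BPWA
    columns: [l1_pre_abi_lar, l1_post_abi_lar, l1_pre_abi_use, l1_post_abi_use,
              l1_family_proficiency, l1_education, l1_exposure, l1_confidence]
  - name: bpwa_l2_luq
    group: BPWA
    columns: [l2_aoa, l2_pre_abi_lar, l2_post_abi_lar, l2_pre_abi_use,
              l2_post_abi_use, l2_family_proficiency, l2_education,
              l2_exposure, l2_confidence]

regressions:
  - name: bpwa_ss_switches
    group: BPWA
    mode: semantic
    y: {dv: n_switches, condition: SS}
    predictors: [bat_l2, rcpm, {pca: bpwa_l1_luq}, {pca: bpwa_l2_luq}]
  - name: bpwa_fs_switches
    group: BPWA
    mode: semantic
    y: {dv: n_switches, condition: FS}
    predictors: [papt, bat_l1, bat_l2, {pca: bpwa_l1_luq}, {pca: bpwa_l2_luq}]
  - name: bpwa_ss_cluster_size
    group: BPWA
    mode: semantic
    y: {dv: mean_cluster_size, condition: SS}
    predictors: [papt, bat_l1, {pca: bpwa_l1_luq}, {pca: bpwa_l2_luq}]
  - name: bpwa_fs_cluster_size
    group: BPWA
    mode: semantic
    y: {dv: mean_cluster_size, condition: FS}
    predictors: [papt, bat_l1, bat_l2, rcpm, {pca: bpwa_l1_luq}]
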