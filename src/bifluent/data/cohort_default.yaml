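# Default synthetic-cohort calibration.
#
# Group x condition targets for mean correct responses (reference means the
# calibration aims at):
#   BPWA: SS 7.34, NS-L1 7.63, NS-L2 5.71, FS 5.31, LF-L1 4.01, LF-L2 3.02
#   HB:   SS 18.05, NS-L1 16.68, NS-L2 15.50, FS 12.64, LF-L1 13.11, LF-L2 10.51
# Within each group, lambda_items and p_continue are constant across the four
# category conditions; condition difficulty enters only through
# p_switch_success and p_language_error.  Questionnaire metrics are planted
# linear factor models (loadings on the z scale; mean/sd rescale to the
# instrument range).
groups:
  BPWA:
    n: 35
    p_l1_spanish: 0.714
    ability_sd: 1.0
    ability_lambda_beta: 0.30
    ability_switch_beta: 0.40
    p_l1_in_self_switch: 0.60
    conditions:
      NS-L1: {lambda_items: 11.0, p_continue: 0.50, p_switch_success: 0.605, p_language_error: 0.02, p_intrusion: 0.03, p_repetition: 0.04, p_paraphasia: 0.03}
      SS:    {lambda_items: 11.0, p_continue: 0.50, p_switch_success: 0.506, p_language_error: 0.00, p_intrusion: 0.03, p_repetition: 0.04, p_paraphasia: 0.03}
      NS-L2: {lambda_items: 11.0, p_continue: 0.50, p_switch_success: 0.339, p_language_error: 0.05, p_intrusion: 0.03, p_repetition: 0.04, p_paraphasia: 0.03}
      FS:    {lambda_items: 11.0, p_continue: 0.50, p_switch_success: 0.274, p_language_error: 0.10, p_intrusion: 0.03, p_repetition: 0.04, p_paraphasia: 0.03}
      LF-L1: {lambda_items: 8.0, p_continue: 0.35, p_switch_success: 0.389, p_language_error: 0.02, p_intrusion: 0.03, p_repetition: 0.04, p_paraphasia: 0.03}
      LF-L2: {lambda_items: 8.0, p_continue: 0.35, p_switch_success: 0.27, p_language_error: 0.04, p_intrusion: 0.03, p_repetition: 0.04, p_paraphasia: 0.03}
    luq:
      L1:
        n_factors: 3
        metrics:
          pre_abi_lar:        {loadings: [0.85, 0.23, -0.01], mean: 93.5, sd: 11.3}
          post_abi_lar:       {loadings: [0.46, -0.08, 0.58], mean: 59.5, sd: 21.3}
          pre_abi_use:        {loadings: [-0.02, 0.90, -0.05], mean: 51.6, sd: 30.0}
          post_abi_use:       {loadings: [0.29, 0.83, 0.14], mean: 65.0, sd: 27.0}
          family_proficiency: {loadings: [-0.08, 0.18, 0.89], mean: 94.5, sd: 12.3}
          education:          {loadings: [0.74, 0.41, 0.08], mean: 72.2, sd: 26.9}
          exposure:           {loadings: [0.50, 0.68, 0.21], mean: 57.6, sd: 20.4}
          confidence:         {loadings: [0.72, 0.03, 0.08], mean: 91.7, sd: 13.6}
      L2:
        n_factors: 2
        metrics:
          aoa:                {loadings: [-0.84, -0.17], mean: 10.5, sd: 7.9, upper: 60.0}
          pre_abi_lar:        {loadings: [0.46, 0.63], mean: 81.6, sd: 17.2}
          post_abi_lar:       {loadings: [0.01, 0.58], mean: 49.7, sd: 20.2}
          pre_abi_use:        {loadings: [0.15, 0.75], mean: 48.4, sd: 30.0}
          post_abi_use:       {loadings: [0.15, 0.77], mean: 35.1, sd: 27.0}
          family_proficiency: {loadings: [0.86, 0.07], mean: 58.6, sd: 32.6}
          education:          {loadings: [0.50, 0.58], mean: 27.8, sd: 26.9}
          exposure:           {loadings: [0.52, 0.69], mean: 42.4, sd: 20.4}
          confidence:         {loadings: [0.85, 0.19], mean: 61.7, sd: 23.4}
    assessments:
      naming_l1: {mean: 56.5, sd: 29.1, ability_loading: 0.7}
      naming_l2: {mean: 42.7, sd: 29.0, ability_loading: 0.7}
      bat_l1:    {mean: 69.1, sd: 26.7, ability_loading: 0.7}
      bat_l2:    {mean: 64.6, sd: 20.3, ability_loading: 0.7}
      papt:      {mean: 89.2, sd: 10.7, ability_loading: 0.5}
      rcpm:      {mean: 74.5, sd: 16.9, ability_loading: 0.4}
  HB:
    n: 22
    p_l1_spanish: 0.955
    ability_sd: 1.0
    ability_lambda_beta: 0.20
    ability_switch_beta: 0.30
    p_l1_in_self_switch: 0.60
    conditions:
      NS-L1: {lambda_items: 22.0, p_continue: 0.55, p_switch_success: 0.654, p_language_error: 0.01, p_intrusion: 0.01, p_repetition: 0.02, p_paraphasia: 0.01}
      SS:    {lambda_items: 22.0, p_continue: 0.55, p_switch_success: 0.67, p_language_error: 0.00, p_intrusion: 0.01, p_repetition: 0.02, p_paraphasia: 0.01}
      NS-L2: {lambda_items: 22.0, p_continue: 0.55, p_switch_success: 0.568, p_language_error: 0.02, p_intrusion: 0.01, p_repetition: 0.02, p_paraphasia: 0.01}
      FS:    {lambda_items: 22.0, p_continue: 0.55, p_switch_success: 0.294, p_language_error: 0.04, p_intrusion: 0.01, p_repetition: 0.02, p_paraphasia: 0.01}
      LF-L1: {lambda_items: 16.0, p_continue: 0.45, p_switch_success: 0.77, p_language_error: 0.01, p_intrusion: 0.01, p_repetition: 0.02, p_paraphasia: 0.01}
      LF-L2: {lambda_items: 16.0, p_continue: 0.45, p_switch_success: 0.594, p_language_error: 0.02, p_intrusion: 0.01, p_repetition: 0.02, p_paraphasia: 0.01}
    luq:
      L1:
        n_factors: 1
        metrics:
          lar:                {loadings: [0.84], mean: 98.0, sd: 5.9}
          use:                {loadings: [0.50], mean: 45.5, sd: 33.4}
          family_proficiency: {loadings: [0.39], mean: 96.9, sd: 12.7}
          education:          {loadings: [0.94], mean: 81.5, sd: 25.2}
          exposure:           {loadings: [0.81], mean: 66.6, sd: 18.8}
          confidence:         {loadings: [0.81], mean: 97.6, sd: 5.5}
      L2:
        n_factors: 2
        metrics:
          aoa:                {loadings: [-0.81, -0.17], mean: 17.0, sd: 11.9, upper: 60.0}
          lar:                {loadings: [0.21, 0.83], mean: 83.1, sd: 16.4}
          use:                {loadings: [-0.05, 0.77], mean: 54.5, sd: 33.4}
          family_proficiency: {loadings: [0.80, -0.04], mean: 43.7, sd: 25.8}
          education:          {loadings: [0.64, 0.58], mean: 18.5, sd: 25.2}
          exposure:           {loadings: [0.58, 0.72], mean: 33.4, sd: 18.8}
          confidence:         {loadings: [0.69, 0.58], mean: 49.5, sd: 27.5}
    assessments:
      naming_l1: {mean: 84.6, sd: 9.6, ability_loading: 0.5}
      naming_l2: {mean: 78.6, sd: 15.5, ability_loading: 0.5}
      bat_l1:    {mean: 92.7, sd: 11.0, ability_loading: 0.5}
      bat_l2:    {mean: 83.5, sd: 17.0, ability_loading: 0.5}
      papt:      {mean: 94.4, sd: 5.7, ability_loading: 0.5}
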