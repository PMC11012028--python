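# Default inputs for the TDAS vs ClinDx cost-utility model.
# Means and standard errors are the published study inputs (USD, annual
# probabilities).  "se: null" on the diagnostic-cost rows means no CI was
# reported; sensitivity analyses use a +/-20% variation for those rows.

diagnostic_phase:
  p_test_positive:   {mean: 0.8990, se: 0.0339, family: beta}
  p_true_positive:   {mean: 0.8286, se: 0.0368, family: beta}
  p_false_positive:  {mean: 0.1961, se: 0.0556, family: beta}
  p_delayed_tdas:    {mean: 0.0071, se: 0.0071, family: beta}
  p_diagnosed_clin:  {mean: 0.6731, se: 0.0376, family: beta}
  p_delayed_clin:    {mean: 0.2000, se: 0.0332, family: beta}

severity_mix_tdas:
  p_mild_tdas:       {mean: 0.1111, se: 0.0786, family: dirichlet, group: mix_tdas}
  p_moderate_tdas:   {mean: 0.5069, se: 0.0585, family: dirichlet, group: mix_tdas}
  p_severe_tdas:     {mean: 0.3819, se: 0.0655, family: dirichlet, group: mix_tdas}

severity_mix_clindx:
  p_mild_clin:       {mean: 0.0608, se: 0.0797, family: dirichlet, group: mix_clin}
  p_moderate_clin:   {mean: 0.3311, se: 0.0672, family: dirichlet, group: mix_clin}
  p_severe_clin:     {mean: 0.6081, se: 0.0515, family: dirichlet, group: mix_clin}

transitions:
  tp_mild_to_moderate:   {mean: 0.0620, se: 0.0538, family: beta}
  tp_mild_to_severe:     {mean: 0.0000, se: null,   family: fixed}
  tp_moderate_to_mild:   {mean: 0.2643, se: 0.0226, family: beta}
  tp_moderate_to_severe: {mean: 0.0218, se: 0.0087, family: beta}
  tp_severe_to_mild:     {mean: 0.0025, se: 0.0044, family: beta}
  tp_severe_to_moderate: {mean: 0.2078, se: 0.1730, family: beta}

mortality:
  rr_asd: {mean: 2.370, se: 0.0942, family: lognormal}

utilities:
  u_mild:     {mean: 0.8659, se: 0.0085, family: beta}
  u_moderate: {mean: 0.8410, se: 0.0098, family: beta}
  u_severe:   {mean: 0.7930, se: 0.0177, family: beta}

direct_medical:
  c_inpatient_mild:       {mean: 387, se: 88, family: gamma}
  c_inpatient_moderate:   {mean: 416, se: 38, family: gamma}
  c_inpatient_severe:     {mean: 664, se: 53, family: gamma}
  p_admission:            {mean: 0.3460, se: 0.0280, family: beta}
  p_admitted_mild:        {mean: 0.0585, se: null, family: fixed}
  p_admitted_moderate:    {mean: 0.3032, se: null, family: fixed}
  p_admitted_severe:      {mean: 0.6383, se: null, family: fixed}
  c_outpatient_mild:      {mean: 66,  se: 11, family: gamma}
  # 133 per the input table; the narrative text prints 113 for the same item.
  c_outpatient_moderate:  {mean: 133, se: 7,  family: gamma}
  c_outpatient_severe:    {mean: 124, se: 12, family: gamma}
  c_instruments_mild:     {mean: 11,  se: 26, family: gamma}
  c_instruments_moderate: {mean: 197, se: 24, family: gamma}
  c_instruments_severe:   {mean: 199, se: 25, family: gamma}
  p_instruments_mild:     {mean: 0.5565, se: null, family: fixed}
  p_instruments_moderate: {mean: 0.6852, se: null, family: fixed}
  p_instruments_severe:   {mean: 0.8966, se: null, family: fixed}
  c_activities_mild:      {mean: 1314, se: 246, family: gamma}
  c_activities_moderate:  {mean: 1148, se: 188, family: gamma}
  c_activities_severe:    {mean: 1152, se: 216, family: gamma}
  p_activities_mild:      {mean: 0.2114, se: null, family: fixed}
  p_activities_moderate:  {mean: 0.2243, se: null, family: fixed}
  p_activities_severe:    {mean: 0.4561, se: null, family: fixed}

direct_nonmedical:
  c_travel_outpatient:        {mean: 13, se: 0.9, family: gamma}
  c_food_outpatient:          {mean: 8,  se: 0.5, family: gamma}
  c_accommodation_outpatient: {mean: 24, se: 3.6, family: gamma}
  p_accommodation_outpatient: {mean: 0.60, se: 0.03, family: beta}
  n_outpatient_visits_mild:     {mean: 5.13, se: 0.49, family: gamma}
  n_outpatient_visits_moderate: {mean: 4.89, se: 0.48, family: gamma}
  n_outpatient_visits_severe:   {mean: 6.65, se: 0.91, family: gamma}
  c_caregiver_outpatient:     {mean: 38, se: 3, family: gamma}
  c_travel_admission_patient:        {mean: 48, se: 6,   family: gamma}
  c_food_admission_patient:          {mean: 9,  se: 0.7, family: gamma}
  c_accommodation_admission_patient: {mean: 15, se: 1,   family: gamma}
  p_accommodation_admission:         {mean: 0.385, se: 0.078, family: beta}
  c_travel_admission_caregiver:        {mean: 63,  se: 10, family: gamma}
  c_food_admission_caregiver:          {mean: 80,  se: 8,  family: gamma}
  c_accommodation_admission_caregiver: {mean: 183, se: 48, family: gamma}
  c_caregiver_admission:               {mean: 225, se: 105, family: gamma}
  n_admissions_per_year:               {mean: 1, se: null, family: fixed}

caregiver_home:
  c_hired_caregiver: {mean: 196, se: 32, family: gamma}
  p_hired_caregiver: {mean: 0.058, se: null, family: fixed}
  c_lost_income:     {mean: 518, se: 53, family: gamma}
  p_quit_mild:       {mean: 0.1778, se: null, family: fixed}
  p_quit_moderate:   {mean: 0.1348, se: null, family: fixed}
  p_quit_severe:     {mean: 0.2364, se: null, family: fixed}

diagnostic_costs:
  c_tdas_training:    {mean: 151,  se: null, family: gamma}
  c_tdas_instruments: {mean: 323,  se: null, family: gamma}
  c_tdas_maintenance: {mean: 0.27, se: null, family: gamma}
  c_cloud:            {mean: 1.43, se: null, family: gamma}
  c_labor_tdas:       {mean: 134,  se: null, family: gamma}
  c_labor_clin:       {mean: 61,   se: null, family: gamma}
  n_diagnoses_per_week:      {mean: 2.0, se: null, family: fixed}
  # Decision parameter: diagnoses over which per-provider TDAS set-up costs
  # (training, instruments) are spread = 2/week x 52 weeks.
  n_amortization_diagnoses:  {mean: 104, se: null, family: fixed}

# Alternative ClinDx severity mix excluding the specialty child-development
# hospital (scenario analysis).
scenario_clindx_mix: {mild: 0.1139, moderate: 0.4557, severe: 0.4304}

economics:
  discount_rate: 0.03
  wtp_thb: 160000.0
  exchange_rate: 34.995
  wtp_usd_override: null
  start_age: 3.52
  max_age: 100
  psa_iterations: 10000
  psa_seed: null
  default_cv: 0.20

flags:
  u_non_asd: 0.0
  renormalize_tp_fp: true
  instruments_one_time: true
  half_cycle: false
  fp_workup_cost: 0.0
  rr_se_log_scale: false

# null / "bundled" -> packaged synthetic Thai-like period life table; replace
# with a CSV path (columns age,qx) to use a real national period life table.
life_table: bundled
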