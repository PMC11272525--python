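# Default inputs for the CTC-vs-SGP cost-effectiveness analysis:
# camrelizumab + paclitaxel + carboplatin (CTC) versus sintilimab +
# gemcitabine + platinum (SGP), first-line advanced squamous NSCLC,
# Chinese payer perspective.  All monetary values are USD (converted from
# CNY at the rate recorded in metadata); times are months unless noted.
# Every {baseline, low, high} triple is a sensitivity-analysis parameter.

metadata:
  reference: CTC
  comparator: SGP
  currency: USD
  cny_per_usd: 6.73

settings:
  cycle_length_days: 21
  n_cycles: 173
  annual_discount: {baseline: 0.05, low: 0.03, high: 0.08}
  wtp_low: 12734.0          # 1x 2022 GDP per capita, Chinese mainland
  wtp_high: 38202.0         # 3x
  cycle_eval: midpoint      # midpoint | start  (half-cycle correction)
  ae_cost_mode: per_cycle   # per_cycle | one_off
  ae_disutility_mode: per_cycle   # per_cycle | induction_only
  hr_direction: divide      # comparator hazard = reference hazard / HR(ref vs comp)
  hr_sampling: lognormal    # lognormal | natural

survival:   # reference-arm Weibull S(t) = exp(-scale * t^shape), t in months
  pfs: {scale: 0.04, shape: 1.28}
  os:  {scale: 0.01, shape: 1.53}

hazard_ratios:   # pooled HR of the reference arm relative to the comparator
  pfs: {baseline: 0.75, low: 0.60, high: 0.94}
  os:  {baseline: 0.95, low: 0.71, high: 1.28}

drug_costs:      # USD per 21-day cycle (BSA 1.73 m2 dosing behind the prices)
  camrelizumab: {baseline: 382.86, low: 306.29, high: 459.43}
  sintilimab:   {baseline: 320.95, low: 256.76, high: 385.14}
  carboplatin:  {baseline: 46.00,  low: 28.17,  high: 149.78}
  cisplatin:    {baseline: 17.83,  low: 9.36,   high: 413.97}
  gemcitabine:  {baseline: 50.55,  low: 38.51,  high: 728.69}
  paclitaxel:   {baseline: 936.11, low: 101.04, high: 1042.47}

ae_costs:        # management cost per episode, USD (grade >= 3, plus grade-2 RCCEP)
  neutropenia:      {baseline: 115.01,  low: 51.11,   high: 357.80}
  leukopenia:       {baseline: 115.01,  low: 51.11,   high: 357.80}
  anemia:           {baseline: 138.75,  low: 106.73,  high: 160.10}
  thrombocytopenia: {baseline: 1505.92, low: 1240.17, high: 1771.67}
  pneumonitis:      {baseline: 242.83,  low: 77.56,   high: 2644.56}
  rccep:            {baseline: 467.64,  low: 327.35,  high: 654.70}

utilities:
  pfs: {baseline: 0.75, low: 0.71, high: 0.85}
  pd:  {baseline: 0.59, low: 0.47, high: 0.71}

disutilities:
  neutropenia:      {baseline: 0.20, low: 0.16,  high: 0.24}
  leukopenia:       {baseline: 0.20, low: 0.16,  high: 0.24}
  anemia:           {baseline: 0.11, low: 0.088, high: 0.132}
  thrombocytopenia: {baseline: 0.07, low: 0.056, high: 0.084}
  pneumonitis:      {baseline: 0.05, low: 0.04,  high: 0.06}
  # range as published; it does not bracket the point value
  rccep:            {baseline: 0.10, low: 0.16,  high: 0.24}

strategies:
  CTC:
    induction: [camrelizumab, paclitaxel, carboplatin]   # cycles 1-6
    maintenance: camrelizumab        # until the PD-1 cap
    maintenance_cap_months: 24
    ae_incidence:
      neutropenia:      {baseline: 0.55, low: 0.44,  high: 0.66}
      leukopenia:       {baseline: 0.30, low: 0.24,  high: 0.36}
      anemia:           {baseline: 0.10, low: 0.08,  high: 0.12}
      thrombocytopenia: {baseline: 0.07, low: 0.056, high: 0.084}
      pneumonitis:      {baseline: 0.04, low: 0.032, high: 0.048}
      rccep:            {baseline: 0.11, low: 0.088, high: 0.132}
  SGP:
    induction: [sintilimab, gemcitabine, cisplatin]      # cisplatin default platinum
    maintenance: sintilimab
    maintenance_cap_months: 24
    ae_incidence:
      neutropenia:      {baseline: 0.49, low: 0.392, high: 0.588}
      leukopenia:       {baseline: 0.36, low: 0.288, high: 0.432}
      anemia:           {baseline: 0.34, low: 0.272, high: 0.408}
      thrombocytopenia: {baseline: 0.45, low: 0.36,  high: 0.54}
      pneumonitis:      {baseline: 0.14, low: 0.112, high: 0.168}
      rccep:            {baseline: 0.0,  low: 0.0,   high: 0.0}
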