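# Diagnostic criteria registry: glucose thresholds in mmol/L following a
# 75 g oral glucose load. Lower bounds are inclusive (>=); values above an
# upper bound are flagged as overt diabetes but still count as positive.
# timing: which visits the reference diagnosis may use
#   late  - 30-32 week OGTT only
#   any   - any pregnancy OGTT (14-16 or 30-32 weeks)
#   y5    - 5-year postpartum follow-up OGTT
WHO1999:
  two_hour_low: 7.8
  timing: late
IADPSG2010:
  fasting_low: 5.1
  fasting_high: 6.9
  one_hour: 10.0
  two_hour_low: 8.5
  two_hour_high: 11.0
  timing: late
  uses_early_fpg: true
WHO2013:
  fasting_low: 5.1
  fasting_high: 6.9
  one_hour: 10.0
  two_hour_low: 8.5
  two_hour_high: 11.0
  timing: any
NORWAY2017:
  fasting_low: 5.3
  two_hour_low: 9.0
  timing: late
PREDIAB_ADA:
  fasting_low: 5.6
  fasting_high: 6.9
  two_hour_low: 7.8
  two_hour_high: 11.0
  timing: y5
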