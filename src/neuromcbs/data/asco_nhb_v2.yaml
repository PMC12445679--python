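# ASCO value framework v2 net-health-benefit parameterisation.
# Point formulas transcribed from the cited ASCO v2 framework publication
# (Schnipper et al., J Clin Oncol 2016): clinical benefit scales the
# treatment effect by the endpoint's importance weight (OS > PFS > RR) and
# is capped; the toxicity component rewards/penalises the relative
# difference in grade 3-4 toxicity between arms; bonus points apply in the
# advanced-disease setting only.  Caps are chosen so the components sum
# exactly to the setting maximum: advanced 80 + 20 + 30 = 130,
# adjuvant 80 + 20 = 100.
framework: asco_nhb_v2
clinical_benefit:
  os_hr_weight: 100    # points per unit (1 - HR) when OS drives the score
  pfs_hr_weight: 80
  rr_weight: 0.6       # points per percentage-point ORR difference
  cap: 80
toxicity:
  max_points: 20       # +/- cap, scaled by relative grade 3-4 differential
bonus:                 # advanced setting only
  tail_of_curve: 20
  palliation: 10
  qol_improved: 10
  treatment_free_interval: 10
  cap: 30
settings:
  advanced:
    max_total: 130
    bonus_allowed: true
  adjuvant:
    max_total: 100
    bonus_allowed: false
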