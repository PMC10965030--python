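# Synthetic 40-item deficit battery: illustrative coding rules spanning the
# usual FI dimensions. Cutoffs are synthetic, not any survey's coding.
- item_id: srh
  kind: categorical
  description: Self-rated health (synthetic coding)
  mapping:
    excellent: 0.0
    very_good: 0.0
    good: 0.0
    fair: 0.5
    poor: 1.0
- item_id: dx_heart_disease
  kind: threshold
  cutoff: 1
  direction: ge
  description: Diagnosed heart disease (1=yes)
- item_id: dx_hypertension
  kind: threshold
  cutoff: 1
  direction: ge
  description: Diagnosed hypertension (1=yes)
- item_id: dx_stroke
  kind: threshold
  cutoff: 1
  direction: ge
  description: Diagnosed stroke (1=yes)
- item_id: dx_diabetes
  kind: threshold
  cutoff: 1
  direction: ge
  description: Diagnosed diabetes (1=yes)
- item_id: dx_lung_disease
  kind: threshold
  cutoff: 1
  direction: ge
  description: Diagnosed lung disease (1=yes)
- item_id: dx_cancer
  kind: threshold
  cutoff: 1
  direction: ge
  description: Diagnosed cancer (1=yes)
- item_id: dx_ulcer
  kind: threshold
  cutoff: 1
  direction: ge
  description: Diagnosed ulcer (1=yes)
- item_id: dx_arthritis
  kind: threshold
  cutoff: 1
  direction: ge
  description: Diagnosed arthritis (1=yes)
- item_id: dx_osteoporosis
  kind: threshold
  cutoff: 1
  direction: ge
  description: Diagnosed osteoporosis (1=yes)
- item_id: dx_hip_fracture
  kind: threshold
  cutoff: 1
  direction: ge
  description: Diagnosed hip fracture (1=yes)
- item_id: adl_dressing
  kind: threshold
  cutoff: 1
  direction: ge
  description: Difficulty with dressing (1=yes)
- item_id: adl_walking_room
  kind: threshold
  cutoff: 1
  direction: ge
  description: Difficulty with walking room (1=yes)
- item_id: adl_bathing
  kind: threshold
  cutoff: 1
  direction: ge
  description: Difficulty with bathing (1=yes)
- item_id: adl_eating
  kind: threshold
  cutoff: 1
  direction: ge
  description: Difficulty with eating (1=yes)
- item_id: adl_bed_transfer
  kind: threshold
  cutoff: 1
  direction: ge
  description: Difficulty with bed transfer (1=yes)
- item_id: adl_toileting
  kind: threshold
  cutoff: 1
  direction: ge
  description: Difficulty with toileting (1=yes)
- item_id: iadl_map_orientation
  kind: threshold
  cutoff: 1
  direction: ge
  description: Difficulty with map orientation (1=yes)
- item_id: iadl_meal_prep
  kind: threshold
  cutoff: 1
  direction: ge
  description: Difficulty with meal prep (1=yes)
- item_id: iadl_shopping
  kind: threshold
  cutoff: 1
  direction: ge
  description: Difficulty with shopping (1=yes)
- item_id: iadl_phone
  kind: threshold
  cutoff: 1
  direction: ge
  description: Difficulty with phone (1=yes)
- item_id: iadl_medications
  kind: threshold
  cutoff: 1
  direction: ge
  description: Difficulty with medications (1=yes)
- item_id: iadl_money
  kind: threshold
  cutoff: 1
  direction: ge
  description: Difficulty with money (1=yes)
- item_id: mob_walk_100m
  kind: threshold
  cutoff: 1
  direction: ge
  description: 'Mobility limitation: walk 100m (1=yes)'
- item_id: mob_sit_2h
  kind: threshold
  cutoff: 1
  direction: ge
  description: 'Mobility limitation: sit 2h (1=yes)'
- item_id: mob_rise_chair
  kind: threshold
  cutoff: 1
  direction: ge
  description: 'Mobility limitation: rise chair (1=yes)'
- item_id: mob_climb_stairs
  kind: threshold
  cutoff: 1
  direction: ge
  description: 'Mobility limitation: climb stairs (1=yes)'
- item_id: mob_stoop
  kind: threshold
  cutoff: 1
  direction: ge
  description: 'Mobility limitation: stoop (1=yes)'
- item_id: mob_reach_arms
  kind: threshold
  cutoff: 1
  direction: ge
  description: 'Mobility limitation: reach arms (1=yes)'
- item_id: mob_lift_5kg
  kind: threshold
  cutoff: 1
  direction: ge
  description: 'Mobility limitation: lift 5kg (1=yes)'
- item_id: mob_pick_coin
  kind: threshold
  cutoff: 1
  direction: ge
  description: 'Mobility limitation: pick coin (1=yes)'
- item_id: moderate_activity
  kind: categorical
  description: Engagement in moderate-energy activities (synthetic coding)
  mapping:
    often: 0.0
    sometimes: 0.5
    rarely: 1.0
    never: 1.0
- item_id: appetite_reduced
  kind: threshold
  cutoff: 1
  direction: ge
  description: Reduced appetite (1=yes)
- item_id: fatigue
  kind: threshold
  cutoff: 1
  direction: ge
  description: Experienced fatigue (1=yes)
- item_id: vision_distance
  kind: categorical
  description: Distance vision with correction (synthetic coding)
  mapping:
    excellent: 0.0
    very_good: 0.0
    good: 0.0
    fair: 0.5
    poor: 1.0
- item_id: vision_close
  kind: categorical
  description: Close vision with correction (synthetic coding)
  mapping:
    excellent: 0.0
    very_good: 0.0
    good: 0.0
    fair: 0.5
    poor: 1.0
- item_id: hearing
  kind: categorical
  description: Hearing with aid if used (synthetic coding)
  mapping:
    excellent: 0.0
    very_good: 0.0
    good: 0.0
    fair: 0.5
    poor: 1.0
- item_id: orientation_errors
  kind: threshold
  cutoff: 1
  direction: ge
  description: Orientation errors (date/month/year/day), 1+ = deficit (synthetic cutoff)
- item_id: bmi
  kind: categorical
  description: BMI deficit category (synthetic coding)
  mapping:
    normal: 0.0
    underweight: 1.0
    overweight: 0.5
    obese: 1.0
- item_id: grip_strength_kg
  kind: threshold
  cutoff: 20
  direction: le
  description: 'Weak grip strength, kg (synthetic cutoff: deficit if <= 20)'
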