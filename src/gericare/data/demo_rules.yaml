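# Illustrative care-plan ruleset.
#
# A production facility maintains its own staff-written ruleset (on the
# order of dozens of rules); this shipped set is a small demonstration
# written over the same 21-variable patient schema and the same four plan
# actions.  Evaluation is most-severe-action first, then priority, then id;
# anything unmatched falls back to "continue_current_treatment".
default: continue_current_treatment
rules:
  # --- emergencies -> extra_situation ---
  - id: extra-fall
    if:
      - {var: MoveH, op: eq, value: "falling on the ground"}
    then: extra_situation
    priority: 100
  - id: extra-unconscious
    if:
      - {var: Con, op: eq, value: "unconscious"}
    then: extra_situation
    priority: 90
  - id: extra-apnoea-desaturation
    if:
      - {var: Breath, op: eq, value: "with apnoeas"}
      - {var: Sat, op: eq, value: "<94%"}
    then: extra_situation
    priority: 80
  - id: extra-hypoglycaemia
    if:
      - {var: Gly, op: eq, value: "<2.5 mmol/l"}
      - {var: Con, op: eq, value: "changed"}
    then: extra_situation
    priority: 70

  # --- plan changes -> adjust ---
  - id: adjust-severe-hypertension
    if:
      - {var: BP, op: eq, value: "hypertension severe"}
    then: adjust
    priority: 60
  - id: adjust-unbearable-pain
    if:
      - {var: Pain, op: eq, value: "unbearable"}
    then: adjust
    priority: 55
  - id: adjust-rapid-weight-loss
    if:
      - {var: BMI, op: eq, value: ">1 minus"}
    then: adjust
    priority: 50
  - id: adjust-bedsores-bedbound
    if:
      - {var: Bedsores, op: eq, value: "yes"}
      - {var: MoveC, op: eq, value: "lying"}
    then: adjust
    priority: 45
  - id: adjust-parenteral-constipation
    if:
      - {var: EatH, op: eq, value: "parenteral nutrition"}
      - {var: Bowel, op: eq, value: "constipation"}
    then: adjust
    priority: 40

  # --- closer observation -> monitor ---
  - id: monitor-desaturation
    if:
      - {var: Sat, op: eq, value: "<94%"}
    then: monitor
    priority: 30
  - id: monitor-sleep-apnoea
    if:
      - {var: Sleep, op: eq, value: "apnoea"}
    then: monitor
    priority: 28
  - id: monitor-hypothermia
    if:
      - {var: Temp, op: eq, value: "<36.0 C"}
    then: monitor
    priority: 26
  - id: monitor-low-grade-fever
    if:
      - {var: Temp, op: eq, value: "37.5-38.0 C"}
    then: monitor
    priority: 25
  - id: monitor-fever
    if:
      - {var: Temp, op: eq, value: ">38.0 C"}
    then: monitor
    priority: 25
  - id: monitor-tachycardia-high-risk
    if:
      - {var: PL, op: eq, value: "tachycardia"}
      - {var: RiskC, op: eq, value: "high"}
    then: monitor
    priority: 24
  - id: monitor-low-fluid-concentrated
    if:
      - {var: Fluid, op: eq, value: "<500 mL"}
      - {var: Urine, op: eq, value: "concentrated urine"}
    then: monitor
    priority: 22
  - id: monitor-diarrhoea-liquids
    if:
      - {var: Bowel, op: eq, value: "diarrhoea"}
      - {var: EatC, op: eq, value: "swallows only liquids"}
    then: monitor
    priority: 20
  - id: monitor-habit-slowdown-high-risk
    if:
      - {var: MoveH, op: eq, value: "slowed down"}
      - {var: RiskC, op: eq, value: "high"}
    then: monitor
    priority: 18
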