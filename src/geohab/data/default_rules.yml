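# Worked default classification rule set for synthetic landscapes. Rules
# are conjunctions of predicates over named co-registered layers (relief in
# meters, elev in meters, slope_deg in degrees, slope_position codes
# 0 flat / 1 ridge / 2 slope / 3 toe-slope / 4 valley, water 1/0).
# Higher priority wins on contested cells. Substitute a territory-specific
# file for real landscapes.
rules:
  - type_name: Water and lake
    code: 6
    priority: 60
    conditions:
      - {layer: water, op: eq, value: 1}
  - type_name: Fluvial landform
    code: 3
    priority: 50
    conditions:
      - {layer: slope_position, op: eq, value: 4}
  - type_name: Mountains
    code: 1
    priority: 40
    conditions:
      - {layer: relief, op: gt, value: 50}
  - type_name: Drainage divide
    code: 5
    priority: 30
    conditions:
      - {layer: slope_position, op: eq, value: 1}
  - type_name: Low gentle slope
    code: 4
    priority: 20
    conditions:
      - {layer: slope_deg, op: gt, value: 2}
      - {layer: relief, op: le, value: 50}
  - type_name: Plains
    code: 2
    priority: 10
    conditions:
      - {layer: relief, op: le, value: 50}
      - {layer: slope_deg, op: le, value: 2}
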