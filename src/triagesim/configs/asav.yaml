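# Amberg-Schwandorf Algorithm for Primary Triage (ASAV), transcribed as a
# declarative decision tree.  ASAV is a functional derivative of mSTART and
# belongs to the START algorithm family; node order and cut-offs below follow
# the family-standard sieve (walking test; life-saving bleeding control;
# breathing after airway opening; respiratory-rate cut-off 30/min; radial
# pulse; consciousness), with the two simulated life-saving interventions
# (bleeding control, oropharyngeal tube) annotated on the edges that
# indicate them.  Categories: RED = I immediate, YELLOW = II delayed,
# GREEN = III minor, DEAD = black.
name: asav
root: walk
findings:
  can_walk: {type: bool}
  severe_bleeding: {type: bool}
  spontaneous_breathing: {type: bool}
  breathing_after_airway_opening: {type: bool}
  respiratory_rate: {type: int, min: 0, max: 80}
  pulse_status: {type: enum, values: [radial_palpable, radial_absent]}
  consciousness: {type: enum, values: [alert_obeys, impaired]}
nodes:
  - id: walk
    finding: can_walk
    edges:
      - {when: true, category: GREEN}
      - {when: false, next: bleeding}
  - id: bleeding
    finding: severe_bleeding
    edges:
      - {when: true, category: RED, intervention: BLEEDING_CONTROL}
      - {when: false, next: breathing}
  - id: breathing
    finding: spontaneous_breathing
    edges:
      - {when: true, next: resp_rate}
      - {when: false, next: airway}
  - id: airway
    finding: breathing_after_airway_opening
    edges:
      - {when: true, category: RED, intervention: OROPHARYNGEAL_TUBE}
      - {when: false, category: DEAD}
  - id: resp_rate
    finding: respiratory_rate
    edges:
      - {when: {ge: 30}, category: RED}
      - {when: {lt: 30}, next: pulse}
  - id: pulse
    finding: pulse_status
    edges:
      - {when: radial_absent, category: RED}
      - {when: radial_palpable, next: awareness}
  - id: awareness
    finding: consciousness
    edges:
      - {when: impaired, category: RED}
      - {when: alert_obeys, category: YELLOW}
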