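# Minimal START-style demonstration tree: walking test, breathing check with
# airway opening, respiratory-rate sieve.  Shipped to show that the engine is
# algorithm-agnostic; not a full transcription of START.
name: start_demo
root: walk
findings:
  can_walk: {type: bool}
  spontaneous_breathing: {type: bool}
  breathing_after_airway_opening: {type: bool}
  respiratory_rate: {type: int, min: 0, max: 80}
nodes:
  - id: walk
    finding: can_walk
    edges:
      - {when: true, category: GREEN}
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
      - {when: {lt: 30}, category: YELLOW}
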