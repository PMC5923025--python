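# triagesim

Primary triage — the first rapid sorting of casualties into urgency
categories at a mass casualty incident (MCI) — is performed with
standardized decision trees of the START family (START, mSTART, ASAV, ...).
How fast do these skills decay after training, and what does a brief yearly
re-training buy back?  `triagesim` is a simulation and evaluation toolkit
for exactly this kind of dummy-based triage-assessment study, aimed at EMS
educators and researchers who design, power, or analyze such studies.

It provides:

- **A configurable triage decision engine.**  Any START-family algorithm is
  a small YAML document (nodes test one finding each; leaves carry a
  category RED/I, YELLOW/II, GREEN/III, DEAD; edges may indicate one of the
  two life-saving interventions, bleeding control or an oropharyngeal
  tube).  An ASAV transcription and a small START demo are shipped; the
  loader proves acyclicity, reachability and predicate totality, so the
  engine can never dead-end.
- **A synthetic cohort simulator.**  Vignette pools with consented
  ground-truth categories, two-person teams that swap leader/assistant
  roles after 10 of 20 patients, per-provider skill reliabilities
  `p_s(t) = floor + (p_base − floor)·e^{−rate·Δt}` that decay over months
  and recover after a re-training event, per-category lognormal triage
  times, roster attrition, and an early-stopping rule on the pass rate.
- **The evaluation and statistics layer.**  The five-class triage error
  taxonomy (OK / over / under / critical over / critical under — any missed
  RED patient is critical under-triage, any non-RED patient tagged RED is
  critical over-triage), accuracy, sensitivity/specificity for RED
  patients, intervention-decision accuracy, Wilson 95% CIs, the 10-item
  performance score (6 leader + 4 assistant items per procedure, maximum
  100 over a 20-procedure session, ≥ 90 = qualified), pass rates, the team
  qualification probability `1 − (1 − p)^k`, triage times re-weighted to an
  idealized 20/20/60 red/yellow/green casualty mix, and the comparison
  suite (one-way ANOVA with Bonferroni post-hoc tests on procedure-derived
  endpoints; paired t and Wilcoxon signed-rank on provider-level scores and
  pass indicators; Shapiro–Wilk normality checks).

## Worked example

```python
import triagesim as ts

tree = ts.load_bundled_tree("asav")
v = {"can_walk": False, "severe_bleeding": False, "spontaneous_breathing": False,
     "breathing_after_airway_opening": True, "respiratory_rate": 0,
     "pulse_status": "radial_palpable", "consciousness": "impaired"}
d = ts.apply_algorithm(v, tree)
print(d.category.value, sorted(i.value for i in d.interventions), d.tag)
# RED ['OROPHARYNGEAL_TUBE'] red

study = ts.simulate_study(ts.StudyConfig(), seed=17)
print({k: round(v, 2) for k, v in study.pass_rates.items()})
# {'s1': 0.88, 's2': 0.45, 's3': 0.94}
print(study.stop_rule_triggered)
# {'s1': False, 's2': True, 's3': False}
print(study.n1, study.n2)
# 620 19
```

The first block triages one vignette: the patient cannot walk, has no
severe bleeding and no spontaneous breathing, but breathes after the airway
is opened — category RED with an oropharyngeal tube indicated, tagged red.
The second block simulates the default three-wave study (baseline,
follow-up at 14.6 months, re-training immediately before a third wave at
25.1 months): the provider pass rate falls from 0.88 to 0.45 — tripping the
70% early-stopping rule — and recovers to 0.94 after the brief re-training.
`n1`/`n2` are the procedure and provider counts after the inclusion rule
(a triage run counts only if a team member attended both the baseline and a
follow-up).

The same pipeline is available from the shell:

```bash
triage simulate --config src/triagesim/configs/study_demo.yaml --seed 17 --out study/
triage run-algorithm --tree asav --vignettes study/vignettes.csv --out decisions.csv
triage evaluate --records study/records.csv --out metrics.csv --report metrics.md
triage compare --study study/ --alpha 0.05 --out comparisons.csv
triage report --study study/ --out report.md
```

All artifacts are plain CSV; `triage report` renders a markdown summary
with Part A (procedure-level) and Part B (provider-level) blocks and
⇑/⇓ direction markers on significant changes.

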