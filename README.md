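# sbirtkit

A tested, reusable engine for stage-based SBIRT (Screening, Brief
Intervention, and Referral to Treatment) in primary care:

* **Screening** (`sbirtkit.screening`) — a 9-substance involvement screen
  with per-substance skip patterns (up to 7 items each), configurable
  item weights, 0–39 involvement scores, and validated risk bands:
  low (0–3), moderate (4–26), high (27+), plus a display-only "none"
  band for substances never used. Weights and the skip table live in an
  editable YAML document (`sbirtkit/data/assist_v3.yaml`).
* **Tailoring** (`sbirtkit.tailoring`) — the five-step session flow:
  risk chart, target-drug selection (highest score, harm-ranking
  tie-breakers, low-risk patients screened out), track assignment,
  readiness staging (precontemplation → maintenance from intention
  windows / time since change), three stage-matched change-process
  modules, a stage-matched goal menu with a simple when/where/how plan,
  and a treatment-readiness branch whenever the target-drug score
  reaches 27.
* **Content library** (`sbirtkit.content`, `sbirtkit.readability`) —
  tagged templates (session feedback, text messages, web activities,
  provider scripts) validated for coverage of every required
  (risk × stage × purpose × channel) cell and for a Flesch-Kincaid
  grade ≤ 5.0 on patient-facing text, under a fully documented
  tokenizer/syllable heuristic.
* **Scheduling** (`sbirtkit.scheduling`) — a deterministic 30-day
  message schedule with stage-dependent cadence (gaps of 1–3 days),
  exactly four weekly web-activity links, seeded template rotation, and
  appointment reminders on configurable lead days (default 3 and 1 days
  before).
* **Dashboard** (`sbirtkit.dashboard`) — session store with
  name+date-of-birth lookup, provider dashboard rendering with
  stage-matched scripts, printable provider summaries and patient
  reports as structured text documents, and audited provider overrides
  (retarget drug, force treatment branch, request restaging).
* **Acceptability scoring** (`sbirtkit.acceptability`) — 5-point Likert
  item means and sample SDs, overall statistics across item means,
  extremes, and a ≥ 4.0 benchmark verdict (half-up one-decimal
  rounding).
* **Synthetic cohort** (`sbirtkit.cohort`) — deterministic generators
  for interviews hitting exact target scores (lexicographic search over
  the weight table), staging answers realizing any stage, and Likert
  responses hitting target item means; includes a four-patient pilot
  fixture (target-drug scores 21/30 opioids and 27/29 cocaine).

## CLI

```bash
sbirtkit simulate --out-dir cohort --seed 7            # synthetic patients + surveys
sbirtkit tailor --interview cohort/patient-2-interview.json \
    --staging cohort/patient-2-staging.json \
    --treatment-staging cohort/patient-2-treatment-staging.json \
    --out session.json
sbirtkit schedule --session session.json --start 2021-03-01 \
    --seed 4 --appointment 2021-03-10 --out sched.json --csv sched.csv
sbirtkit validate-content                              # coverage + readability
sbirtkit report --session session.json --mode patient_report
sbirtkit eval --responses cohort/survey-responses.csv  # Likert benchmark
```

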